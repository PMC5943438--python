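"""Comparison statistics: Welch t, Cohen's d, percent difference, ANCOVA."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pwsfield.groupstats import (
    ancova,
    cohens_d,
    comparison_table,
    percent_difference,
    welch_t,
)

sample = arrays(
    float,
    st.integers(3, 12),
    elements=st.floats(0.1, 10, allow_nan=False),
).filter(lambda a: a.var() > 1e-8)


class TestWelch:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a.copy())
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_large_sample_consistency(self, rng):
        """Calibrated control-no vs control-high populations separate
        decisively at n=10^6."""
        from pwsfield.cohort import invert_group_moments

        m = invert_group_moments(-0.866, 37.2)
        a = rng.normal(m.mean_a, m.pooled_sd, 10**6)
        b = rng.normal(m.mean_b, m.pooled_sd, 10**6)
        _, _, p = welch_t(a, b)
        assert p < 1e-6

    def test_agrees_with_exact_permutation_oracle(self):
        """On a 12-observation toy, the Welch p matches the exact
        permutation null of the Welch statistic."""
        a = np.array([1.1, 2.3, 1.9, 2.8, 1.5, 2.2])
        b = np.array([2.6, 3.1, 2.0, 3.4, 2.9, 3.8])
        t_obs, _, p_welch = welch_t(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        total = 0
        for idx in itertools.combinations(range(12), 6):
            mask = np.zeros(12, dtype=bool)
            mask[list(idx)] = True
            ta, _, _ = welch_t(pooled[mask], pooled[~mask])
            count += abs(ta) >= abs(t_obs) - 1e-12
            total += 1
        p_perm = count / total
        assert p_welch == pytest.approx(p_perm, abs=0.03)

    def test_swap_invariance(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 15)
        assert welch_t(a, b)[2] == pytest.approx(welch_t(b, a)[2])


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a.copy()) == 0.0

    def test_two_point_hand_computation(self):
        # s_a = s_b = sqrt(2) with ddof=1, so pooled SD = sqrt(2) and
        # d = (1 - 2)/sqrt(2)
        assert cohens_d([0.0, 2.0], [1.0, 3.0]) == pytest.approx(-1 / np.sqrt(2))

    def test_calibrated_population_recovery(self, rng):
        from pwsfield.cohort import invert_group_moments

        m = invert_group_moments(-0.866, 37.2)
        a = rng.normal(m.mean_a, m.pooled_sd, 10**6)
        b = rng.normal(m.mean_b, m.pooled_sd, 10**6)
        assert cohens_d(a, b) == pytest.approx(-0.866, abs=0.01)

    @given(a=sample, b=sample)
    def test_antisymmetry_and_scale_invariance(self, a, b):
        try:
            d = cohens_d(a, b)
        except ValueError:
            return
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-9, abs=1e-12)
        assert cohens_d(3.0 * a, 3.0 * b) == pytest.approx(d, rel=1e-9, abs=1e-12)


class TestPercentDifference:
    def test_identical_means_zero(self):
        assert percent_difference([1.0, 3.0], [2.0, 2.0]) == 0.0

    def test_means_one_and_three(self):
        assert percent_difference([1.0, 1.0], [3.0, 3.0]) == pytest.approx(100.0)

    def test_calibrated_population_recovery(self, rng):
        from pwsfield.cohort import invert_group_moments

        m = invert_group_moments(-0.807, 40.2)
        a = rng.normal(m.mean_a, m.pooled_sd, 10**6)
        b = rng.normal(m.mean_b, m.pooled_sd, 10**6)
        assert percent_difference(a, b) == pytest.approx(40.2, abs=0.2)

    @given(a=sample, b=sample)
    def test_antisymmetry_and_scale_invariance(self, a, b):
        try:
            p = percent_difference(a, b)
        except ValueError:
            return
        assert percent_difference(b, a) == pytest.approx(-p, rel=1e-9, abs=1e-12)
        assert percent_difference(2 * a, 2 * b) == pytest.approx(p, rel=1e-9, abs=1e-9)

    def test_zero_average_rejected(self):
        with pytest.raises(ValueError):
            percent_difference([-1.0, -1.0], [1.0, 1.0])


class TestAncova:
    def test_perfect_predictor_p_near_zero(self, rng):
        group = np.repeat(["a", "b"], 30)
        ld = rng.normal(np.where(group == "a", 1.0, 1.5), 0.3)
        p = ancova(ld, group, ld + rng.normal(0, 1e-9, 60))
        assert p < 1e-10

    def test_null_covariate_nonsignificant_typically(self, rng):
        group = np.repeat(["a", "b", "c"], 20)
        ld = rng.normal(1.0, 0.3, 60)
        cov = rng.normal(50, 10, 60)
        p = ancova(ld, group, cov)
        assert 0 < p <= 1

    def test_null_p_uniform(self, rng):
        """Type-I calibration: under an independent covariate the partial-F
        p-value is Uniform(0,1) (KS test over replicates)."""
        from scipy import stats as sps

        pvals = []
        for _ in range(300):
            group = np.repeat(["a", "b", "c"], 15)
            ld = rng.normal(np.tile([1.0, 1.3, 1.6], 15), 0.4, 45)
            cov = rng.normal(0, 1, 45)
            pvals.append(ancova(ld, group, cov))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_categorical_covariate(self, rng):
        group = np.repeat(["a", "b"], 25)
        ld = rng.normal(1.0, 0.2, 50)
        smoking = rng.choice(["current", "former", "never"], 50)
        p = ancova(ld, group, smoking, categorical=True)
        assert 0 < p <= 1

    def test_constant_covariate_rejected(self, rng):
        group = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError):
            ancova(rng.normal(size=20), group, np.ones(20))

    def test_collinear_design_rejected(self, rng):
        group = np.repeat(["a", "b"], 10)
        cov = np.where(group == "a", 0.0, 1.0)
        with pytest.raises(ValueError):
            ancova(rng.normal(size=20), group, cov)


class TestComparisonTable:
    def test_default_cohort_table_shape_and_signs(self, patient_table):
        table = comparison_table(patient_table)
        assert len(table) == 6
        assert set(table.columns) >= {"p_value", "effect_size", "pct_difference"}
        # published sign convention: larger second group means negative d,
        # positive percent difference
        row = table.iloc[0]
        assert np.sign(row["effect_size"]) == -np.sign(row["pct_difference"])

    def test_advanced_adenoma_contrast_uses_group8_counts(self, patient_table):
        table = comparison_table(patient_table)
        aa_row = table[table["group_a"] == "aa_no"].iloc[0]
        assert aa_row["n_a"] == 23
        assert aa_row["n_b"] == 16
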