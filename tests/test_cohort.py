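"""Synthetic cohort: moment inversion, sizes, demographics, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pwsfield.cohort import (
    CohortConfig,
    cohort_to_frame,
    default_cohort_config,
    default_group_sizes,
    frame_to_csv_bytes,
    generate_cohort,
    invert_group_moments,
)
from pwsfield.groupstats import cohens_d, percent_difference


class TestInvertGroupMoments:
    @pytest.mark.parametrize(
        "d, pct, mean_b, pooled_sd",
        [
            (-0.866, 37.2, 1.4570, 0.5277),
            (-0.807, 40.2, 1.5031, 0.6235),
            (-0.698, 37.1, 1.4555, 0.6526),
            (-0.342, 17.4, 1.1906, 0.5573),
        ],
    )
    def test_closed_form_inversion(self, d, pct, mean_b, pooled_sd):
        m = invert_group_moments(d, pct, mean_a=1.0)
        assert m.mean_b == pytest.approx(mean_b, abs=5e-5)
        assert m.pooled_sd == pytest.approx(pooled_sd, abs=5e-5)

    @given(
        d=st.floats(-3, 3).filter(lambda v: abs(v) > 1e-3),
        pct=st.floats(-150, 150).filter(lambda v: abs(v) > 1e-3),
    )
    def test_analytic_round_trip(self, d, pct):
        """Re-deriving (d, %) from the inverted moments recovers the inputs."""
        if np.sign(d) == np.sign(pct):
            with pytest.raises(ValueError):
                invert_group_moments(d, pct)
            return
        m = invert_group_moments(d, pct)
        d_back = (m.mean_a - m.mean_b) / m.pooled_sd
        pct_back = 100 * (m.mean_b - m.mean_a) / ((m.mean_a + m.mean_b) / 2)
        assert d_back == pytest.approx(d, rel=1e-9)
        assert pct_back == pytest.approx(pct, rel=1e-9)

    def test_simulation_round_trip(self, rng):
        """10^6 normal draws per group recover (d, %) to sampling precision."""
        m = invert_group_moments(-0.866, 37.2)
        a = rng.normal(m.mean_a, m.pooled_sd, 10**6)
        b = rng.normal(m.mean_b, m.pooled_sd, 10**6)
        assert cohens_d(a, b) == pytest.approx(-0.866, abs=0.01)
        assert percent_difference(a, b) == pytest.approx(37.2, abs=0.2)

    @pytest.mark.parametrize(
        "d, pct",
        [(0.0, 37.2), (-0.8, 200.0), (-0.8, -250.0), (-0.8, 0.0)],
    )
    def test_degenerate_inputs_rejected(self, d, pct):
        with pytest.raises(ValueError):
            invert_group_moments(d, pct)


class TestGroupSizes:
    def test_total_is_190(self):
        assert sum(default_group_sizes().values()) == 190

    def test_published_decomposition(self):
        sizes = default_group_sizes()
        assert sizes["control_no"] == 95
        assert sizes["control_high_aa"] + sizes["control_high_crc"] == 10
        assert sizes["control_high_crc"] == 4
        assert sizes["nda_no"] + sizes["aa_no"] == 36
        assert sizes["aa_no"] == 23
        assert sizes["nda_high"] == 3
        assert sizes["nda_high"] + sizes["aa_high_aa"] + sizes["aa_high_crc"] == 19
        low = sizes["control_low"] + sizes["nda_low"] + sizes["aa_low"]
        assert low == 30


class TestGenerateCohort:
    def test_default_cohort_size_and_groups(self, default_cohort):
        assert len(default_cohort) == 190
        by6 = {}
        for p in default_cohort:
            by6[p.group6] = by6.get(p.group6, 0) + 1
        assert by6 == {
            "control_no": 95, "control_low": 10, "control_high": 10,
            "adenoma_no": 36, "adenoma_low": 20, "adenoma_high": 19,
        }

    def test_empty_config_gives_empty_cohort(self):
        cfg = default_cohort_config()
        cfg.group_sizes = {k: 0 for k in cfg.group_sizes}
        assert generate_cohort(cfg) == []

    def test_determinism_byte_identical_csv(self):
        a = frame_to_csv_bytes(cohort_to_frame(generate_cohort(default_cohort_config(seed=7))))
        b = frame_to_csv_bytes(cohort_to_frame(generate_cohort(default_cohort_config(seed=7))))
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(default_cohort_config(seed=1))
        b = generate_cohort(default_cohort_config(seed=2))
        assert any(x.age != y.age or x.true_mean_ld != y.true_mean_ld
                   for x, y in zip(a, b))

    def test_cell_lds_positive_and_counted(self, default_cohort):
        for p in default_cohort:
            assert p.cell_lds.size == 40
            assert np.all(p.cell_lds > 0)
            assert p.age >= 18

    def test_demographic_calibration(self, default_cohort):
        """Group age means land within 2*SD/sqrt(n) of their targets."""
        targets = {
            "control_no": (55, 11), "control_low": (66, 6),
            "control_high": (63, 16), "adenoma_no": (61, 9),
            "adenoma_low": (67, 12), "adenoma_high": (68, 11),
        }
        by6 = {}
        for p in default_cohort:
            by6.setdefault(p.group6, []).append(p.age)
        for g, ages in by6.items():
            mean, sd = targets[g]
            tol = 2 * sd / np.sqrt(len(ages))
            assert abs(np.mean(ages) - mean) <= tol + 0.5  # +0.5 for rounding

    def test_negative_group_size_rejected(self):
        cfg = default_cohort_config()
        cfg.group_sizes["control_no"] = -1
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_bad_probability_rejected(self):
        cfg = default_cohort_config()
        cfg.demographics["control_no"] = (55, 11, 147, 12, 23, 68)
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_history_and_current_axes_independent(self, default_cohort):
        combos = {(p.history, p.current) for p in default_cohort}
        # CRC history co-occurs with current control (and current AA) —
        # history and current status are separate axes
        assert ("high_risk_CRC", "control") in combos
        assert ("high_risk_CRC", "AA") in combos


class TestMomentsCalibration:
    def test_group_means_consistent_with_printed_ratios(self):
        """Chained group means reproduce every printed (d, %) pair's ratio."""
        cfg = default_cohort_config()
        mu = cfg.group_ld_mean
        mean6 = {
            "control_no": mu["control_no"],
            "control_low": mu["control_low"],
            "control_high": mu["control_high"],
            "adenoma_no": (13 * mu["nda_no"] + 23 * mu["aa_no"]) / 36,
            "adenoma_low": (10 * mu["nda_low"] + 10 * mu["aa_low"]) / 20,
            "adenoma_high": (3 * mu["nda_high"] + 16 * mu["aa_high"]) / 19,
        }
        pairs = [
            ("control_no", "control_high", 37.2),
            ("control_no", "adenoma_no", 17.4),
            ("control_low", "adenoma_low", 14.4),
            ("adenoma_no", "adenoma_high", 40.2),
        ]
        for ga, gb, pct in pairs:
            ma, mb = mean6[ga], mean6[gb]
            assert 100 * (mb - ma) / ((ma + mb) / 2) == pytest.approx(pct, abs=0.05)
        maa, mab = mu["aa_no"], mu["aa_high"]
        assert 100 * (mab - maa) / ((maa + mab) / 2) == pytest.approx(37.1, abs=0.05)
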