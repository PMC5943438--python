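"""Group-comparison statistics on per-patient mean disorder strength.

Implements the comparison toolkit of the study: two-tailed Welch t-test
(unequal variances, Satterthwaite degrees of freedom), Cohen's d with the
pooled-SD definition, percent difference (difference of means over their
average), and single-covariate ANCOVA confounder checks.

Sign conventions follow the published comparison table: for an ordered
pair (first, second), d = (mean_first - mean_second) / pooled SD and
%diff = 100 * (mean_second - mean_first) / mean of the two means, so a
second group with larger L_d yields a negative d and a positive percent
difference.  Statistics operate on per-patient means (one observation per
patient), matching the published group Ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupComparison",
    "welch_t",
    "cohens_d",
    "percent_difference",
    "compare",
    "ancova",
    "comparison_table",
    "ancova_table",
    "DEFAULT_COMPARISONS",
]

#: The published comparison table's ordered group pairs, on the coarse
#: six-group labels plus the advanced-adenoma-only contrast.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("control_no", "control_high"),
    ("control_no", "adenoma_no"),
    ("control_low", "adenoma_low"),
    ("control_high", "adenoma_high"),
    ("adenoma_no", "adenoma_high"),
    ("aa_no", "aa_high"),
)


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    p_value: float
    effect_size: float
    pct_difference: float


def _as_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    return a, b


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-tailed Welch t-test; returns (t, Satterthwaite df, p)."""
    a, b = _as_samples(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(a, b) -> float:
    """(mean_a - mean_b) / pooled SD with the (n-1)-weighted pooled variance."""
    a, b = _as_samples(a, b)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def percent_difference(a, b) -> float:
    """100 * (mean_b - mean_a) / mean of the two means (signed percent)."""
    a, b = _as_samples(a, b)
    avg = (a.mean() + b.mean()) / 2.0
    if avg == 0:
        raise ValueError("average of means is zero")
    return float(100.0 * (b.mean() - a.mean()) / avg)


def compare(group_a: str, group_b: str, a, b) -> GroupComparison:
    a, b = _as_samples(a, b)
    _, _, p = welch_t(a, b)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=a.size,
        n_b=b.size,
        p_value=p,
        effect_size=cohens_d(a, b),
        pct_difference=percent_difference(a, b),
    )


def ancova(ld, group, covariate, covariate_name: str = "covariate",
           categorical: bool | None = None) -> float:
    """Partial F-test p-value for one covariate, adjusting for group.

    Fits OLS ``ld ~ C(group) + covariate`` and returns the type-II
    ANOVA p-value of the covariate term.  ``categorical`` forces the
    covariate encoding; by default non-numeric covariates are treated as
    factors.
    """
    ld = np.asarray(ld, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate)
    if np.unique(group).size < 2:
        raise ValueError("need at least 2 groups")
    if np.unique(covariate).size < 2:
        raise ValueError("covariate does not vary")
    if categorical is None:
        categorical = not np.issubdtype(covariate.dtype, np.number)
    df = pd.DataFrame({"ld": ld, "group": group, "cov": covariate})
    term = "C(cov)" if categorical else "cov"
    model = smf.ols(f"ld ~ C(group) + {term}", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("collinear design: covariate confounded with group labels")
    anova = sm.stats.anova_lm(model, typ=2)
    return float(anova.loc[term, "PR(>F)"])


def comparison_table(
    patient_table: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
) -> pd.DataFrame:
    """Comparison-table analogue from a per-patient frame.

    ``patient_table`` needs columns ``group`` (six-group label), ``group8``
    and ``mean_ld``.  Pairs naming ``aa_*``/``nda_*`` groups select on the
    eight-group label.
    """
    rows = []
    for ga, gb in comparisons:
        col_a = "group8" if ga.startswith(("aa_", "nda_")) else "group"
        col_b = "group8" if gb.startswith(("aa_", "nda_")) else "group"
        a = patient_table.loc[patient_table[col_a] == ga, "mean_ld"].to_numpy()
        b = patient_table.loc[patient_table[col_b] == gb, "mean_ld"].to_numpy()
        c = compare(ga, gb, a, b)
        rows.append((ga, gb, c.n_a, c.n_b, c.p_value, c.effect_size, c.pct_difference))
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "n_a", "n_b", "p_value",
                 "effect_size", "pct_difference"],
    )


def ancova_table(patient_table: pd.DataFrame) -> pd.DataFrame:
    """Confounder-check analogue: one ANCOVA p-value per demographic factor.

    Covariates are tested one at a time (age numeric; sex and alcohol as
    2-level factors; smoking as a 3-level factor), adjusting for the
    six-group membership.
    """
    factors = {
        "age": (patient_table["age"].to_numpy(float), False),
        "sex": (patient_table["sex"].to_numpy(), True),
        "smoking": (patient_table["smoking"].to_numpy(), True),
        "alcohol": (patient_table["alcohol_user"].astype(str).to_numpy(), True),
    }
    ld = patient_table["mean_ld"].to_numpy(float)
    grp = patient_table["group"].to_numpy()
    rows = [
        (name, ancova(ld, grp, cov, categorical=cat))
        for name, (cov, cat) in factors.items()
    ]
    return pd.DataFrame(rows, columns=["factor", "ancova_p"])
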