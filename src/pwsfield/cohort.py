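"""Synthetic patient cohort generator.

Builds a 190-patient colonoscopy cohort with six history/current-status
groups whose disorder-strength (L_d) moments, group sizes and demographics
match the published summary statistics of the rectal-brushing PWS study
this package models.  Only group-level summaries of that study are public:
per-group L_d means are therefore recovered from the printed effect sizes
(Cohen's d, pooled-SD definition) and percent differences via
:func:`invert_group_moments`, with the control/no-history group mean
normalized to 1.

Patients carry two independent axes:

* ``history`` — colonic history: none, low-risk (nondiminutive adenoma,
  5–10 mm), or high-risk (advanced adenoma or prior colorectal cancer);
* ``current`` — current colonoscopy finding: control (no adenoma),
  nondiminutive adenoma (NDA) or advanced adenoma (AA).

Six coarse groups cross {control, adenoma} with {no, low, high} history;
the eight-group analysis used for the risk correlation additionally splits
current adenomas into NDA/AA, dropping the 3-patient NDA/high cell.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupMoments",
    "PatientRecord",
    "CohortConfig",
    "invert_group_moments",
    "default_group_sizes",
    "default_cohort_config",
    "generate_cohort",
    "cohort_to_frame",
    "patient_frame",
    "GROUPS6",
    "GROUPS8",
]

#: Six coarse groups, in the study's column order.
GROUPS6 = (
    "control_no",
    "control_low",
    "control_high",
    "adenoma_no",
    "adenoma_low",
    "adenoma_high",
)

#: Eight analysis groups (current adenomas split into NDA/AA; the
#: 3-patient nda_high cell is excluded from the risk-correlation fit).
GROUPS8 = (
    "control_no",
    "control_low",
    "control_high",
    "nda_no",
    "nda_low",
    "aa_no",
    "aa_low",
    "aa_high",
)

_HISTORY_LEVEL = {
    "none": "no",
    "low_risk": "low",
    "high_risk_AA": "high",
    "high_risk_CRC": "high",
}

_SMOKING = ("current", "former", "never")


@dataclass(frozen=True)
class GroupMoments:
    """First/second moments of a two-group comparison on normalized L_d."""

    mean_a: float
    mean_b: float
    pooled_sd: float

    def __post_init__(self) -> None:
        if self.pooled_sd <= 0:
            raise ValueError("pooled_sd must be positive")


@dataclass
class PatientRecord:
    patient_id: str
    age: int
    sex: str  # "male" | "female"
    history: str  # "none" | "low_risk" | "high_risk_AA" | "high_risk_CRC"
    current: str  # "control" | "NDA" | "AA"
    smoking: str  # "current" | "former" | "never"
    alcohol_user: bool
    true_mean_ld: float
    cell_lds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def history_level(self) -> str:
        return _HISTORY_LEVEL[self.history]

    @property
    def group6(self) -> str:
        cls = "control" if self.current == "control" else "adenoma"
        return f"{cls}_{self.history_level}"

    @property
    def group8(self) -> str:
        cur = {"control": "control", "NDA": "nda", "AA": "aa"}[self.current]
        return f"{cur}_{self.history_level}"

    @property
    def mean_ld(self) -> float:
        if self.cell_lds.size == 0:
            raise ValueError(f"patient {self.patient_id} has no cell measurements")
        return float(np.mean(self.cell_lds))


def invert_group_moments(
    effect_size: float, pct_diff: float, mean_a: float = 1.0
) -> GroupMoments:
    """Recover two-group population moments from (Cohen's d, % difference).

    With d = (m_a − m_b)/s and %diff = 100·(m_b − m_a)/((m_a + m_b)/2),
    fixing ``mean_a`` gives the closed-form inversion

        m_b = m_a (2 + p) / (2 − p),   p = pct_diff / 100
        s   = (m_a − m_b) / d

    Parameters
    ----------
    effect_size
        Signed Cohen's d (pooled-SD definition); must be nonzero.
    pct_diff
        Signed percent difference; must lie strictly inside (−200, 200)
        and be nonzero (identical means give an undefined pooled SD here).
    mean_a
        Mean of the first group; the normalization anchor.
    """
    if mean_a <= 0:
        raise ValueError("mean_a must be positive")
    if abs(pct_diff) >= 200:
        raise ValueError("pct_diff must lie strictly inside (-200, 200)")
    if effect_size == 0:
        raise ValueError("effect_size must be nonzero (pooled SD would be infinite)")
    p = pct_diff / 100.0
    mean_b = mean_a * (2.0 + p) / (2.0 - p)
    if mean_b == mean_a:
        raise ValueError("identical means: pooled SD degenerate (zero)")
    pooled_sd = (mean_a - mean_b) / effect_size
    if pooled_sd <= 0:
        raise ValueError(
            "effect size and percent difference have inconsistent signs "
            "(implied pooled SD is negative)"
        )
    return GroupMoments(mean_a=mean_a, mean_b=mean_b, pooled_sd=pooled_sd)


def default_group_sizes() -> dict[str, int]:
    """Published-cohort group decomposition (total 190 patients).

    Keys are fine-grained cells: the eight analysis groups, with the
    high-risk-history cells further split by adenoma-vs-CRC history.
    The low-risk split (control 10 / adenoma 20, NDA 10 / AA 10) and the
    CRC-history count inside aa_high (3) are not public and are package
    defaults; everything else is derivable from the published group Ns.
    """
    return {
        "control_no": 95,
        "control_low": 10,
        "control_high_aa": 6,
        "control_high_crc": 4,
        "nda_no": 13,
        "aa_no": 23,
        "nda_low": 10,
        "aa_low": 10,
        "nda_high": 3,
        "aa_high_aa": 13,
        "aa_high_crc": 3,
    }


# Normalized group mean L_d, recovered from the printed effect-size /
# percent-difference pairs (control_no anchored at 1).  NDA/AA subtype
# means inside each adenoma group solve the weighted-average constraints
# with aa_no = 1.25 as the one free choice (see docs/methods.md).
DEFAULT_GROUP_LD_MEAN: dict[str, float] = {
    "control_no": 1.0,
    "control_low": 1.22850,
    "control_high": 1.45700,
    "nda_no": 1.08545,
    "aa_no": 1.25,
    "nda_low": 1.30,
    "aa_low": 1.53826,
    "nda_high": 1.63081,
    "aa_high": 1.81937,
}

# Interpatient SD per coarse group: the pooled SD recovered from the most
# relevant printed comparison (only pooled SDs are recoverable).
DEFAULT_GROUP_LD_SD: dict[str, float] = {
    "control_no": 0.52772,
    "control_low": 0.49418,
    "control_high": 0.52772,
    "adenoma_no": 0.62346,
    "adenoma_low": 0.49418,
    "adenoma_high": 0.62346,
}

# Demographics per coarse group (published study, Table-2 analogue):
# (age_mean, age_sd, %male, %current smoker, %former smoker, %alcohol).
DEFAULT_DEMOGRAPHICS: dict[str, tuple[float, float, float, float, float, float]] = {
    "control_no": (55, 11, 47, 12, 23, 68),
    "control_low": (66, 6, 70, 22, 22, 100),
    "control_high": (63, 16, 40, 20, 30, 20),
    "adenoma_no": (61, 9, 47, 8, 31, 44),
    "adenoma_low": (67, 12, 65, 20, 45, 60),
    "adenoma_high": (68, 11, 42, 0, 32, 37),
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    ``group_sizes`` uses the fine-grained cell keys of
    :func:`default_group_sizes`.  L_d values are normalized so the
    control/no-history group mean is 1.  ``cell_sd`` is the within-patient
    cell-level SD; its default 0.06 keeps the per-patient standard error
    (cell_sd/√cells) below 2% of the interpatient SD at 40 cells/patient.
    """

    group_sizes: dict[str, int] = field(default_factory=default_group_sizes)
    group_ld_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_LD_MEAN)
    )
    group_ld_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_LD_SD)
    )
    demographics: dict[str, tuple[float, float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    cells_per_patient: int = 40
    cell_sd: float = 0.06
    ld_floor: float = 1e-6
    min_age: int = 18
    seed: int = 0

    def validate(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {key!r}")
        if self.cells_per_patient < 1:
            raise ValueError("cells_per_patient must be >= 1")
        if self.cell_sd < 0:
            raise ValueError("cell_sd must be non-negative")
        for g, (_, age_sd, pm, ps, pf, pa) in self.demographics.items():
            if age_sd < 0:
                raise ValueError(f"negative age SD for group {g!r}")
            for name, pct in (("male", pm), ("current-smoker", ps),
                              ("former-smoker", pf), ("alcohol", pa)):
                if not 0 <= pct <= 100:
                    raise ValueError(f"{name} percentage outside [0,100] for {g!r}")
            if ps + pf > 100:
                raise ValueError(f"smoking percentages exceed 100 for {g!r}")

    @property
    def total(self) -> int:
        return sum(self.group_sizes.values())


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


def _cell_spec(key: str) -> tuple[str, str, str]:
    """Map a fine group-size key to (current, history, group6)."""
    table = {
        "control_no": ("control", "none"),
        "control_low": ("control", "low_risk"),
        "control_high_aa": ("control", "high_risk_AA"),
        "control_high_crc": ("control", "high_risk_CRC"),
        "nda_no": ("NDA", "none"),
        "aa_no": ("AA", "none"),
        "nda_low": ("NDA", "low_risk"),
        "aa_low": ("AA", "low_risk"),
        "nda_high": ("NDA", "high_risk_AA"),
        "aa_high_aa": ("AA", "high_risk_AA"),
        "aa_high_crc": ("AA", "high_risk_CRC"),
    }
    if key not in table:
        raise KeyError(f"unknown group-size key {key!r}")
    current, history = table[key]
    cls = "control" if current == "control" else "adenoma"
    return current, history, f"{cls}_{_HISTORY_LEVEL[history]}"


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort.

    Per patient: age ~ round(Normal(group mean, SD)) floored at
    ``min_age``; sex/smoking/alcohol from per-group categorical rates;
    true mean L_d ~ Normal(subtype mean, group interpatient SD); per-cell
    L_d = true mean + Normal(0, cell_sd).  Simulated L_d is floored at a
    small positive value (disorder strength is a physical length scale).
    """
    config = config or default_cohort_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    idx = 0
    for key in sorted(config.group_sizes):
        n = config.group_sizes[key]
        current, history, group6 = _cell_spec(key)
        cur8 = {"control": "control", "NDA": "nda", "AA": "aa"}[current]
        group8 = f"{cur8}_{_HISTORY_LEVEL[history]}"
        mu = config.group_ld_mean[group8]
        sd = config.group_ld_sd[group6]
        age_mean, age_sd, pm, ps, pf, pa = config.demographics[group6]
        for _ in range(n):
            idx += 1
            age = max(config.min_age, int(round(rng.normal(age_mean, age_sd))))
            sex = "male" if rng.random() < pm / 100.0 else "female"
            smoking = rng.choice(
                _SMOKING, p=[ps / 100.0, pf / 100.0, 1.0 - (ps + pf) / 100.0]
            )
            alcohol = bool(rng.random() < pa / 100.0)
            true_ld = max(config.ld_floor, rng.normal(mu, sd))
            cells = true_ld + rng.normal(0.0, config.cell_sd, config.cells_per_patient)
            cells = np.maximum(cells, config.ld_floor)
            patients.append(
                PatientRecord(
                    patient_id=f"P{idx:04d}",
                    age=age,
                    sex=sex,
                    history=history,
                    current=current,
                    smoking=str(smoking),
                    alcohol_user=alcohol,
                    true_mean_ld=true_ld,
                    cell_lds=cells,
                )
            )
    return patients


def cohort_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """One row per cell measurement (long format, CSV-ready)."""
    rows = []
    for p in patients:
        for j, ld in enumerate(p.cell_lds):
            rows.append(
                (p.patient_id, p.group6, p.group8, p.history, p.current, p.age,
                 p.sex, p.smoking, p.alcohol_user, j, float(ld))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "group", "group8", "history", "current", "age",
            "sex", "smoking", "alcohol_user", "cell_index", "ld",
        ],
    )


def patient_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient with mean L_d and its standard error."""
    rows = []
    for p in patients:
        cells = np.asarray(p.cell_lds, dtype=float)
        se = float(np.std(cells, ddof=1) / np.sqrt(cells.size)) if cells.size > 1 else 0.0
        rows.append(
            (p.patient_id, p.group6, p.group8, p.history, p.current, p.age,
             p.sex, p.smoking, p.alcohol_user, cells.size, p.mean_ld, se)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "group", "group8", "history", "current", "age",
            "sex", "smoking", "alcohol_user", "n_cells", "mean_ld", "se_ld",
        ],
    )


def frame_to_csv_bytes(frame: pd.DataFrame) -> bytes:
    """Deterministic CSV serialization (UTF-8, '.' decimal, header)."""
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["demographics"] = {k: list(v) for k, v in d["demographics"].items()}
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "demographics" in d:
        d["demographics"] = {k: tuple(v) for k, v in d["demographics"].items()}
    return CohortConfig(**d)
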