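"""Five-year cumulative colorectal-cancer risk meta-model.

Each patient group's risk over a 5-year horizon combines three published
quantities:

* ``AA_r`` — the group's probability of developing a future advanced
  adenoma over a surveillance interval (~3.4 years between surveillance
  colonoscopies);
* ``AA2CRC`` — the per-patient cumulative probability that an advanced
  adenoma progresses to cancer over the remaining 1.6 years, from an
  age- and sex-dependent annual progression rate (roughly 2–6 %/yr);
* ``CRC_m`` — a constant 0.35 %/yr probability of metachronous cancer
  for patients with a cancer history.

Annual rates convert to cumulative probabilities through the exponential
hazard formula 1 - exp(-rate * time).  The group risk is the patient-count
weighted average

    risk = [ AA_r * sum_i AA2CRC_i  +  N_c * (1 - exp(-CRC_m * horizon)) ]
           / (N_a + N_c)

where the sum runs over the N_a patients on the adenoma pathway (no
history or adenoma history) and N_c counts patients with a cancer
history, who contribute only the metachronous term.

The per-group ``AA_r`` values and the age/sex progression table of the
original studies are not public; the defaults shipped here are documented
placeholders with the correct orderings and magnitudes (see
docs/methods.md), exposed in :class:`RiskConfig` for substitution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GROUPS8, PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AA2CRCTable",
    "RiskConfig",
    "GroupRisk",
    "cumulative_risk",
    "aa2crc_patient",
    "group_crc_risk",
    "cohort_group_risks",
    "default_risk_config",
]


@dataclass
class AA2CRCTable:
    """Annual advanced-adenoma-to-cancer progression rate by age band and sex.

    Stored as closed age bands [age_lo, age_hi) with one annual rate per
    (band, sex).  Ages outside the table clamp to the nearest band with a
    logged warning.
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    rate_female: np.ndarray
    rate_male: np.ndarray

    def __post_init__(self) -> None:
        for name in ("age_lo", "age_hi", "rate_female", "rate_male"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.age_lo.size == self.age_hi.size == self.rate_female.size
                == self.rate_male.size > 0):
            raise ValueError("table columns must be equal-length and non-empty")
        if np.any(self.rate_female < 0) or np.any(self.rate_male < 0):
            raise ValueError("annual rates must be non-negative")
        if np.any(np.diff(self.age_lo) <= 0):
            raise ValueError("age bands must be ascending")

    def annual_rate(self, age: float, sex: str) -> float:
        rates = {"male": self.rate_male, "female": self.rate_female}.get(sex)
        if rates is None:
            raise ValueError(f"unknown sex {sex!r}")
        if age < self.age_lo[0] or age >= self.age_hi[-1]:
            logger.warning("age %s outside table range; clamping to nearest band", age)
            idx = 0 if age < self.age_lo[0] else len(rates) - 1
        else:
            idx = int(np.searchsorted(self.age_lo, age, side="right") - 1)
        return float(rates[idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lo, hi, rf, rm in zip(self.age_lo, self.age_hi,
                                  self.rate_female, self.rate_male):
            rows.append((f"{int(lo)}-{int(hi)}", "female", rf))
            rows.append((f"{int(lo)}-{int(hi)}", "male", rm))
        return pd.DataFrame(rows, columns=["age_band", "sex", "annual_rate"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AA2CRCTable":
        bands = sorted(
            {b for b in frame["age_band"]},
            key=lambda b: float(b.split("-")[0]),
        )
        lo = [float(b.split("-")[0]) for b in bands]
        hi = [float(b.split("-")[1]) for b in bands]
        pivot = frame.set_index(["age_band", "sex"])["annual_rate"]
        rf = [float(pivot[(b, "female")]) for b in bands]
        rm = [float(pivot[(b, "male")]) for b in bands]
        return cls(age_lo=lo, age_hi=hi, rate_female=rf, rate_male=rm)


def default_aa2crc_table() -> AA2CRCTable:
    """Placeholder progression table: 5-year bands over ages 40-85.

    Female annual rate rises linearly from 2 %/yr at age 50 to 6 %/yr at
    age 80 (clamped outside); male rates carry a 1.3x multiplier, matching
    the published observation that progression risk is higher in men.
    These are NOT the original study's values (those are unpublished).
    """
    lo = np.arange(40, 85, 5, dtype=float)
    hi = lo + 5
    mid = (lo + hi) / 2
    base = np.clip(0.02 + (mid - 50.0) * (0.04 / 30.0), 0.02, 0.06)
    return AA2CRCTable(age_lo=lo, age_hi=hi, rate_female=base, rate_male=1.3 * base)


#: Placeholder per-group probability of a future advanced adenoma over the
#: ~3.4-year surveillance interval.  Monotone along both axes (history
#: no < low < high; current control < NDA < AA), with current status the
#: stronger predictor, growing roughly geometrically across the risk
#: ordering.  NOT the original meta-analysis values (unpublished).
DEFAULT_AA_R: dict[str, float] = {
    "control_no": 0.030,
    "control_low": 0.050,
    "control_high": 0.086,
    "nda_no": 0.037,
    "nda_low": 0.060,
    "nda_high": 0.128,
    "aa_no": 0.053,
    "aa_low": 0.104,
    "aa_high": 0.198,
}


@dataclass
class RiskConfig:
    aa_r: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_R))
    aa2crc: AA2CRCTable = field(default_factory=default_aa2crc_table)
    crc_m_annual: float = 0.0035
    t_surveillance: float = 3.4
    t_progression: float = 1.6
    horizon: float = 5.0

    def validate(self) -> None:
        for g, p in self.aa_r.items():
            if not 0 <= p <= 1:
                raise ValueError(f"aa_r[{g!r}] outside [0,1]")
        if not 0 <= self.crc_m_annual <= 1:
            raise ValueError("crc_m_annual outside [0,1]")
        if abs(self.t_surveillance + self.t_progression - self.horizon) > 1e-9:
            raise ValueError("t_surveillance + t_progression must equal horizon")


def default_risk_config() -> RiskConfig:
    return RiskConfig()


def cumulative_risk(annual_rate: float, years: float) -> float:
    """Cumulative probability from a constant annual rate: 1 - exp(-rate*t)."""
    if annual_rate < 0 or years < 0:
        raise ValueError("annual_rate and years must be non-negative")
    return float(-np.expm1(-annual_rate * years))


def aa2crc_patient(patient: PatientRecord, config: RiskConfig) -> float:
    """Cumulative AA-to-CRC progression probability for one patient.

    The patient's age/sex annual rate, accumulated over the progression
    window ``t_progression``.
    """
    annual = config.aa2crc.annual_rate(patient.age, patient.sex)
    return cumulative_risk(annual, config.t_progression)


@dataclass(frozen=True)
class GroupRisk:
    group: str
    n_adenoma_path: int
    n_crc_history: int
    risk: float

    def __post_init__(self) -> None:
        if not 0 <= self.risk <= 1:
            raise ValueError("group risk outside [0,1]")


def group_crc_risk(
    patients: list[PatientRecord], config: RiskConfig, group: str | None = None
) -> GroupRisk:
    """Patient-count weighted 5-year group risk (see module docstring)."""
    config.validate()
    if not patients:
        raise ValueError("empty patient group")
    group = group or patients[0].group8
    if group not in config.aa_r:
        raise KeyError(f"no aa_r entry for group {group!r}")
    crc_hist = [p for p in patients if p.history == "high_risk_CRC"]
    adenoma_path = [p for p in patients if p.history != "high_risk_CRC"]
    n_a, n_c = len(adenoma_path), len(crc_hist)
    aa_term = config.aa_r[group] * sum(aa2crc_patient(p, config) for p in adenoma_path)
    crc_term = n_c * cumulative_risk(config.crc_m_annual, config.horizon)
    risk = (aa_term + crc_term) / (n_a + n_c)
    return GroupRisk(group=group, n_adenoma_path=n_a, n_crc_history=n_c, risk=risk)


def cohort_group_risks(
    patients: list[PatientRecord],
    config: RiskConfig | None = None,
    groups: tuple[str, ...] = GROUPS8,
) -> dict[str, GroupRisk]:
    """Group risks for the eight-group analysis breakdown."""
    config = config or default_risk_config()
    by_group: dict[str, list[PatientRecord]] = {}
    for p in patients:
        by_group.setdefault(p.group8, []).append(p)
    out = {}
    for g in groups:
        if g not in by_group:
            raise ValueError(f"cohort has no patients in group {g!r}")
        out[g] = group_crc_risk(by_group[g], config, group=g)
    return out
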