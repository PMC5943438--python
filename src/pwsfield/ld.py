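"""Disorder-strength (L_d) estimation from interference spectra.

L_d quantifies nanoscale refractive-index heterogeneity and equals the
fluctuation variance times the correlation length, sigma2_n * l_c.  It is
estimated per pixel from the variance of the normalized, detrended
interference spectrum: the spectrum is divided by its mean, a degree-1
polynomial in wavenumber is removed (the slowly varying reflectance
baseline), and the residual variance is mapped to L_d through a scalar
calibration obtained from simulated media with known sigma2_n * l_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ImageCube, MediumParams

__all__ = [
    "LdMap",
    "CellMeasurement",
    "spectral_fluctuation",
    "ld_from_spectrum",
    "ld_map",
    "calibrate",
    "aggregate",
    "patient_ld",
    "cohort_qc",
]


@dataclass
class LdMap:
    ld: np.ndarray  # (nx, ny), >= 0
    calibration: float

    def __post_init__(self) -> None:
        self.ld = np.asarray(self.ld, dtype=float)
        if self.ld.ndim != 2:
            raise ValueError("ld map must be 2-D")
        if np.any(self.ld < 0):
            raise ValueError("ld map must be non-negative")


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    mean_ld: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("cell ROI must contain at least one pixel")
        if self.mean_ld < 0:
            raise ValueError("mean_ld must be non-negative")


def _detrend_matrix(wavelengths: np.ndarray) -> np.ndarray:
    """Residual-maker matrix of an OLS fit on [1, wavenumber]."""
    k = 2.0 * np.pi / np.asarray(wavelengths, dtype=float)
    x = np.column_stack([np.ones_like(k), k])
    hat = x @ np.linalg.solve(x.T @ x, x.T)
    return np.eye(k.size) - hat


def spectral_fluctuation(spectrum: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Normalized, detrended spectral fluctuation series.

    The spectrum is divided by its mean (making the statistic invariant to
    overall intensity) and a degree-1 polynomial in wavenumber is removed,
    leaving a zero-mean residual series carrying the interference
    oscillations.
    """
    s = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if s.ndim != 1 or s.size != wavelengths.size:
        raise ValueError("spectrum and wavelength grid must have equal length")
    if s.size < 8:
        raise ValueError("need at least 8 spectral samples")
    m = s.mean()
    if m <= 0:
        raise ValueError("spectrum mean must be positive")
    return _detrend_matrix(wavelengths) @ (s / m)


def ld_from_spectrum(series: np.ndarray, calibration: float = 1.0) -> float:
    """Disorder strength from a fluctuation series: calibration * var(series)."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 samples to estimate a variance")
    if calibration < 0:
        raise ValueError("calibration must be non-negative")
    return float(calibration * np.var(series))


def ld_map(cube: ImageCube, calibration: float = 1.0) -> LdMap:
    """Per-pixel L_d map of an image cube (vectorized over pixels)."""
    nx, ny, nwl = cube.shape
    spectra = cube.reflectance.reshape(nx * ny, nwl)
    means = spectra.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ValueError("all spectra must have positive mean")
    resid = (spectra / means) @ _detrend_matrix(cube.wavelengths).T
    ld = calibration * resid.var(axis=1)
    return LdMap(ld=ld.reshape(nx, ny), calibration=calibration)


def mean_spectral_variance(cube: ImageCube) -> float:
    """Mean over pixels of the detrended spectral-fluctuation variance."""
    return float(ld_map(cube, calibration=1.0).ld.mean())


def calibrate(cubes: list[ImageCube], params: list[MediumParams]) -> float:
    """Through-origin least-squares map from spectral variance to L_d.

    Fits slope c minimizing sum_i (sigma2_i * lc_i - c * v_i)^2 over
    reference cubes with known media, where v_i is the cube's mean
    detrended spectral variance.  Requires at least 3 references spanning
    distinct sigma2_n * l_c products.
    """
    if len(cubes) != len(params):
        raise ValueError("need one MediumParams per reference cube")
    if len(cubes) < 3:
        raise ValueError("need at least 3 reference cubes")
    targets = np.array([p.ld_true for p in params])
    if np.unique(targets).size < 2 or np.all(targets == 0):
        raise ValueError("reference set degenerate: sigma2_n*lc products must vary")
    v = np.array([mean_spectral_variance(c) for c in cubes])
    denom = float(v @ v)
    if denom == 0:
        raise ValueError("reference cubes carry no spectral fluctuation")
    return float((targets @ v) / denom)


def aggregate(ldmap: LdMap, rois: np.ndarray | list[np.ndarray]) -> list[CellMeasurement]:
    """Per-cell mean L_d over region-of-interest masks.

    ``rois`` is either a labelled integer array (0 = background, one
    positive label per cell) of the map's shape, or a list of boolean
    masks.
    """
    masks: list[tuple[int, np.ndarray]]
    if isinstance(rois, np.ndarray) and rois.dtype != bool:
        if rois.shape != ldmap.ld.shape:
            raise ValueError("labelled ROI array must match the map shape")
        labels = np.unique(rois)
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValueError("no ROIs in labelled array")
        masks = [(int(lab), rois == lab) for lab in labels]
    else:
        masks = list(enumerate(rois, start=1))
    out = []
    for cell_id, mask in masks:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ldmap.ld.shape:
            raise ValueError(f"ROI {cell_id} does not match the map shape")
        if not mask.any():
            raise ValueError(f"ROI {cell_id} is empty")
        out.append(
            CellMeasurement(
                cell_id=cell_id,
                mean_ld=float(ldmap.ld[mask].mean()),
                n_pixels=int(mask.sum()),
            )
        )
    return out


def patient_ld(cells: list[CellMeasurement] | np.ndarray) -> tuple[float, float]:
    """Patient mean L_d over cells and its standard error (SD/sqrt(n))."""
    if isinstance(cells, (list, tuple)) and cells and isinstance(cells[0], CellMeasurement):
        values = np.array([c.mean_ld for c in cells], dtype=float)
    else:
        values = np.asarray(cells, dtype=float)
    if values.size == 0:
        raise ValueError("patient has no cell measurements")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, se


def cohort_qc(cell_lds_per_patient: list[np.ndarray]) -> float:
    """Measurement-precision QC ratio, in percent.

    Average intrapatient standard error of the mean L_d divided by the
    interpatient standard deviation of patient means.  Sampling ~40 cells
    per patient should keep this below 2%: patient means are then measured
    much more precisely than they vary across patients.
    """
    if len(cell_lds_per_patient) < 2:
        raise ValueError("need at least 2 patients")
    means, ses = [], []
    for cells in cell_lds_per_patient:
        cells = np.asarray(cells, dtype=float)
        if cells.size < 2:
            raise ValueError("each patient needs at least 2 cells")
        mean, se = patient_ld(cells)
        means.append(mean)
        ses.append(se)
    inter_sd = float(np.std(means, ddof=1))
    if inter_sd == 0:
        raise ValueError("degenerate cohort: zero interpatient SD")
    return 100.0 * float(np.mean(ses)) / inter_sd
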