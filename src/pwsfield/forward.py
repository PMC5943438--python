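"""Forward model for partial-wave spectroscopic (PWS) measurements.

Simulates the backscattered interference spectrum of a weakly scattering
cell: a one-dimensional random refractive-index profile with prescribed
fluctuation variance and exponential correlation interferes with the
strong reference reflection from the cell's top surface.  A single
wavelength-scanned acquisition produces an image cube (x, y, lambda) with
one interference spectrum per pixel; the disorder-strength estimator in
:mod:`pwsfield.ld` is validated against the known product
sigma2_n * l_c of these simulated media.

The scattering treatment is first-order (Born) with a scalar field:
R(lambda) = |r0 + c * sum_z dn(z) exp(i 2 k n0 z) dz|^2.  This preserves
the statistic the analysis relies on — spectral-fluctuation variance
proportional to sigma2_n * l_c in the sub-wavelength correlation regime
(2 k n0 l_c < 1) — without the full vectorial multiple-scattering theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MediumParams",
    "ImageCube",
    "default_wavelengths",
    "simulate_index_profile",
    "interference_spectrum",
    "generate_cube",
]

#: Coupling constant of the Born scattering term, per nm of path.  Small
#: enough that the scattered field stays perturbative against the surface
#: reflection (the cross term dominates the spectral fluctuation); only
#: relative disorder strength matters downstream (cohort L_d values are
#: normalized), so this is a fixed instrument-like constant.
DEFAULT_COUPLING = 0.002

#: Ambient refractive index above the sample (cells measured dry).
AMBIENT_INDEX = 1.0


@dataclass(frozen=True)
class MediumParams:
    """Statistical description of the random refractive-index medium.

    Parameters
    ----------
    sigma2_n
        Variance of the refractive-index fluctuations (dimensionless).
    lc
        Correlation length of the fluctuations, nm (exponential
        autocorrelation exp(-|dz|/lc)).
    n0
        Mean refractive index of the cell (default 1.38).
    thickness
        Cell height, nm.  Must be at least 10*lc so the correlation
        statistics are well sampled within one cell.
    dz
        Axial sampling step, nm.  Must resolve the correlation length
        (dz <= lc/5).
    """

    sigma2_n: float
    lc: float
    n0: float = 1.38
    thickness: float = 2000.0
    dz: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_n < 0:
            raise ValueError("sigma2_n must be non-negative")
        if self.lc <= 0:
            raise ValueError("lc must be positive")
        if self.thickness < 10 * self.lc:
            raise ValueError("thickness must be >= 10*lc to sample the correlation")
        if self.dz > self.lc / 5:
            raise ValueError("dz must be <= lc/5 to resolve the correlation length")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.thickness / self.dz))

    @property
    def ld_true(self) -> float:
        """Ground-truth disorder strength sigma2_n * lc (nm)."""
        return self.sigma2_n * self.lc


@dataclass
class ImageCube:
    """(x, y, lambda) reflectance cube with its wavelength grid."""

    reflectance: np.ndarray  # (nx, ny, n_wavelengths), non-negative
    wavelengths: np.ndarray  # nm, ascending
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be a 3-D (x, y, lambda) array")
        if self.wavelengths.ndim != 1 or self.reflectance.shape[2] != self.wavelengths.size:
            raise ValueError("wavelength grid must match the cube's spectral axis")
        if self.wavelengths.size < 8:
            raise ValueError("need at least 8 spectral samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.reflectance)) or np.any(self.reflectance < 0):
            raise ValueError("reflectance must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape


def default_wavelengths(start: float = 500.0, stop: float = 700.0,
                        step: float = 7.0) -> np.ndarray:
    """Wavelength-scanned acquisition grid: 500–700 nm at 7 nm (29 bands)."""
    n = int(np.floor((stop - start) / step)) + 1
    return start + step * np.arange(n)


def fresnel_amplitude(n0: float, n_ambient: float = AMBIENT_INDEX) -> float:
    """Normal-incidence reflection amplitude at the ambient/cell interface."""
    return (n_ambient - n0) / (n_ambient + n0)


def simulate_index_profile(
    params: MediumParams, seed: int | np.random.Generator = 0, n_profiles: int = 1
) -> np.ndarray:
    """Sample axial refractive-index fluctuation profiles.

    Stationary zero-mean Gaussian sequences with variance ``sigma2_n`` and
    autocorrelation exp(-|dz|/lc), realized as the stationary AR(1)
    recursion dn[i+1] = rho*dn[i] + sqrt(1-rho^2)*sqrt(sigma2_n)*eps[i]
    with rho = exp(-dz/lc) (the discretized Ornstein–Uhlenbeck process).

    Returns an array of shape (n_profiles, n_steps); squeeze to 1-D for a
    single profile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_steps
    if params.sigma2_n == 0:
        out = np.zeros((n_profiles, n))
        return out[0] if n_profiles == 1 else out
    rho = np.exp(-params.dz / params.lc)
    sigma = np.sqrt(params.sigma2_n)
    eps = rng.standard_normal((n_profiles, n))
    out = np.empty((n_profiles, n))
    out[:, 0] = sigma * eps[:, 0]  # stationary start
    innov = np.sqrt(1.0 - rho * rho) * sigma
    for i in range(1, n):
        out[:, i] = rho * out[:, i - 1] + innov * eps[:, i]
    return out[0] if n_profiles == 1 else out


def interference_spectrum(
    profile: np.ndarray,
    wavelengths: np.ndarray,
    n0: float = 1.38,
    dz: float = 1.0,
    coupling: float = DEFAULT_COUPLING,
) -> np.ndarray:
    """Backscattered reflectance spectrum of one (or many) profiles.

    R(lambda) = |r0 + c * sum_z dn(z) exp(i 2 k n0 z) dz|^2 with
    k = 2 pi / lambda and r0 the Fresnel amplitude of the top surface.
    Accepts a 1-D profile or a stack (n_profiles, n_steps); returns a
    spectrum per profile.
    """
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    wavelengths = np.asarray(wavelengths, dtype=float)
    if profile.shape[1] == 0:
        raise ValueError("empty refractive-index profile")
    if wavelengths.ndim != 1 or np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths must be a strictly ascending 1-D grid")
    z = dz * np.arange(profile.shape[1])
    k = 2.0 * np.pi / wavelengths
    phase = np.exp(1j * 2.0 * np.outer(k, z) * n0)  # (n_wl, n_z)
    scatter = coupling * dz * (profile @ phase.T)  # (n_profiles, n_wl)
    r0 = fresnel_amplitude(n0)
    spectra = np.abs(r0 + scatter) ** 2
    return spectra[0] if spectra.shape[0] == 1 else spectra


def generate_cube(
    params: MediumParams,
    nx: int = 32,
    ny: int = 32,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
    coupling: float = DEFAULT_COUPLING,
) -> ImageCube:
    """Simulate an image cube with independent media per pixel.

    Pixels are statistically independent (the analysis averages over
    regions of interest, so lateral correlation is irrelevant here).
    """
    if nx < 1 or ny < 1:
        raise ValueError("cube dimensions must be >= 1")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if wl.size < 8:
        raise ValueError("need at least 8 wavelengths")
    profiles = simulate_index_profile(params, seed=seed, n_profiles=nx * ny)
    profiles = np.atleast_2d(profiles)
    spectra = interference_spectrum(profiles, wl, n0=params.n0, dz=params.dz,
                                    coupling=coupling)
    spectra = np.atleast_2d(spectra)
    cube = spectra.reshape(nx, ny, wl.size)
    meta = {
        "seed": seed,
        "sigma2_n": params.sigma2_n,
        "lc": params.lc,
        "n0": params.n0,
        "thickness": params.thickness,
        "dz": params.dz,
        "coupling": coupling,
    }
    return ImageCube(reflectance=cube, wavelengths=wl, metadata=meta)
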