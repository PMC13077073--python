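"""Sensorless modal adaptive-optics simulation.

Forward model: scalar 2D Fourier optics. A circular pupil carries a phase
that is a sum of Noll-indexed, RMS-normalized Zernike modes; the focal
intensity is |FFT(pupil)|^2 and two-photon excitation goes as its square.
A structured sample is imaged through the two-photon PSF and the mean image
intensity serves as the feedback metric: because two-photon excitation is
nonlinear, a tighter focus concentrates photon density and raises the mean
fluorescence, so the metric peaks when aberrations are compensated.

The optimizer scans each mode's coefficient over a symmetric preset range
(an odd number of evenly spaced steps so that 0 is tested), repeats the scan
over several cycles, averages the metric curves, fixes the best correction,
and moves to the next mode — corrections accumulate sequentially.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Optional

import numpy as np

from .core import ZernikeCoefficients

__all__ = [
    "noll_to_nm",
    "zernike_mode",
    "zernike_basis",
    "zernike_phase",
    "PupilField",
    "make_pupil",
    "two_photon_psf",
    "strehl_ratio",
    "NoiseModel",
    "simulate_image",
    "AoResult",
    "sensorless_optimize",
]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map Noll index j >= 1 to (radial order n, signed azimuthal order m).

    m > 0 pairs with cos(m theta), m < 0 with sin(m theta); the sign follows
    Noll's convention (even j -> cosine, odd j -> sine).
    """
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = int((-1.0 + np.sqrt(8 * (j - 1) + 1)) / 2.0)
    p = j - (n * (n + 1)) // 2
    k = n % 2
    m = ((p + k) // 2) * 2 - k
    if m > 0:
        m = m if j % 2 == 0 else -m
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_mode(j: int, grid_px: int) -> np.ndarray:
    """Noll mode j sampled on a grid_px x grid_px grid over the unit disc.

    RMS-normalized: the RMS of the mode over the pupil is 1 (piston j=1 is
    identically 1). Values outside the pupil are 0.
    """
    n, m = noll_to_nm(j)
    x = (np.arange(grid_px) - (grid_px - 1) / 2) / (grid_px / 2)
    xx, yy = np.meshgrid(x, x)
    rho = np.sqrt(xx**2 + yy**2)
    theta = np.arctan2(yy, xx)
    inside = rho <= 1.0
    r = _radial_poly(n, abs(m), np.where(inside, rho, 0.0))
    if m == 0:
        z = np.sqrt(n + 1.0) * r
    elif m > 0:
        z = np.sqrt(2.0 * (n + 1.0)) * r * np.cos(m * theta)
    else:
        z = np.sqrt(2.0 * (n + 1.0)) * r * np.sin(-m * theta)
    return np.where(inside, z, 0.0)


def zernike_basis(n_modes: int, grid_px: int, start_noll: int = 2) -> np.ndarray:
    """Stack of ``n_modes`` modes starting at Noll index ``start_noll``."""
    max_n = max(noll_to_nm(start_noll + n_modes - 1)[0], 1)
    if grid_px < 4 * max_n:
        raise ValueError(
            f"grid of {grid_px} px cannot resolve radial order {max_n} "
            f"(need >= {4 * max_n} px, ~4 px per fringe at the pupil edge)"
        )
    return np.stack([zernike_mode(j, grid_px) for j in range(start_noll, start_noll + n_modes)])


def zernike_phase(
    coeffs: ZernikeCoefficients,
    grid_px: int,
    basis: Optional[np.ndarray] = None,
    start_noll: int = 2,
) -> np.ndarray:
    """Pupil phase (radians) = sum of c_k Z_k, Noll-indexed from ``start_noll``."""
    if basis is None:
        basis = zernike_basis(coeffs.n_modes, grid_px, start_noll=start_noll)
    if basis.shape[0] != coeffs.n_modes:
        raise ValueError("basis/coefficient length mismatch")
    return np.tensordot(coeffs.coeffs, basis, axes=1)


@dataclass
class PupilField:
    """Circular pupil with a phase map; the Fourier-optics forward model input."""

    grid_px: int
    phase: np.ndarray
    na: float = 0.5
    wavelength_um: float = 0.92
    amplitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.amplitude is None:
            x = (np.arange(self.grid_px) - (self.grid_px - 1) / 2) / (self.grid_px / 2)
            xx, yy = np.meshgrid(x, x)
            self.amplitude = (xx**2 + yy**2 <= 1.0).astype(float)
        inside = self.amplitude > 0
        if not np.all(np.isfinite(self.phase[inside])):
            raise ValueError("pupil phase must be finite inside the aperture")


def make_pupil(
    coeffs: ZernikeCoefficients,
    grid_px: int = 64,
    na: float = 0.5,
    wavelength_um: float = 0.92,
    basis: Optional[np.ndarray] = None,
    start_noll: int = 2,
) -> PupilField:
    phase = zernike_phase(coeffs, grid_px, basis=basis, start_noll=start_noll)
    return PupilField(grid_px=grid_px, phase=phase, na=na, wavelength_um=wavelength_um)


def two_photon_psf(
    pupil: PupilField, pad_factor: int = 2, normalize: bool = True
) -> np.ndarray:
    """Two-photon excitation PSF from a pupil field.

    One-photon focal intensity is |FFT(A e^{i phi})|^2 on a zero-padded grid
    (pad_factor >= 2 to avoid aliasing), normalized to unit sum (the
    excitation light carries fixed average power regardless of aberration).
    The two-photon excitation profile is its square: fluorescence scales
    with the square of the photon density, so its TOTAL depends on the
    aberration — a tighter focus excites more fluorescence. With
    ``normalize=True`` (default) the returned PSF is rescaled to unit sum
    (the shape-only PSF); ``normalize=False`` keeps the physical total,
    which is what makes mean image intensity a usable feedback metric.
    """
    if pad_factor < 2:
        raise ValueError("pad_factor must be >= 2 to avoid aliasing")
    n = pupil.grid_px
    big = n * pad_factor
    field_arr = np.zeros((big, big), dtype=complex)
    lo = (big - n) // 2
    field_arr[lo : lo + n, lo : lo + n] = pupil.amplitude * np.exp(1j * pupil.phase)
    focal = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field_arr)))
    psf1 = np.abs(focal) ** 2
    psf1 /= psf1.sum()
    psf2 = psf1**2
    if normalize:
        psf2 = psf2 / psf2.sum()
    return psf2


def strehl_ratio(pupil: PupilField, pad_factor: int = 2) -> float:
    """Peak one-photon focal intensity relative to the unaberrated pupil."""
    flat = PupilField(
        grid_px=pupil.grid_px,
        phase=np.zeros_like(pupil.phase),
        na=pupil.na,
        wavelength_um=pupil.wavelength_um,
        amplitude=pupil.amplitude,
    )

    def _peak(p: PupilField) -> float:
        n = p.grid_px
        big = n * pad_factor
        arr = np.zeros((big, big), dtype=complex)
        lo = (big - n) // 2
        arr[lo : lo + n, lo : lo + n] = p.amplitude * np.exp(1j * p.phase)
        return float(np.abs(np.fft.fft2(arr)).max() ** 2)

    return _peak(pupil) / _peak(flat)


@dataclass
class NoiseModel:
    """Photon (Poisson) and read (Gaussian) noise for simulated images.

    ``photons_per_unit`` converts the noiseless image (arbitrary units) to
    expected photon counts; None disables photon noise entirely.
    """

    photons_per_unit: Optional[float] = None
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.photons_per_unit is not None and self.photons_per_unit <= 0:
            raise ValueError("photon budget must be positive")


def simulate_image(
    sample: np.ndarray,
    psf: np.ndarray,
    noise_model: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, float]:
    """Image the sample through the two-photon PSF; return (image, metric).

    The metric is the mean pixel intensity of the image — the feedback
    signal of the sensorless optimization. Convolution is FFT-based with
    'same' output size.
    """
    from scipy.signal import fftconvolve

    image = fftconvolve(sample, psf, mode="same")
    if noise_model is not None and (
        noise_model.photons_per_unit is not None or noise_model.read_noise_sd > 0
    ):
        if rng is None:
            rng = np.random.default_rng()
        if noise_model.photons_per_unit is not None:
            lam = np.clip(image * noise_model.photons_per_unit, 0, None)
            image = rng.poisson(lam).astype(float) / noise_model.photons_per_unit
        if noise_model.read_noise_sd > 0:
            image = image + rng.normal(0, noise_model.read_noise_sd, image.shape)
    return image, float(image.mean())


@dataclass
class AoResult:
    """Outcome of a sensorless modal optimization run."""

    corrections: ZernikeCoefficients  # accumulated per-mode corrections
    residual: ZernikeCoefficients  # true aberration + corrections
    metric_trajectory: np.ndarray  # one metric value per coefficient transition
    transitions: int
    mode_scans: list[dict]  # per mode: tested values + averaged metric curve
    initial_metric: float
    final_metric: float
    range_limited: bool = False


def sensorless_optimize(
    sample: np.ndarray,
    true_aberration: ZernikeCoefficients,
    n_modes: Optional[int] = None,
    steps: int = 21,
    cycles: int = 5,
    scan_range: float = 1.5,
    noise_model: Optional[NoiseModel] = None,
    seed: int = 0,
    grid_px: int = 64,
    pad_factor: int = 2,
    start_noll: int = 2,
    n_passes: int = 1,
) -> AoResult:
    """Sequential mode-by-mode sensorless correction.

    For each mode (in Noll order from ``start_noll``; pass 4 to skip
    tip/tilt, which only translate the image and leave the mean-intensity
    metric flat) the correction coefficient is stepped over ``steps`` evenly
    spaced values spanning ±``scan_range`` rad RMS, in each of ``cycles``
    passes; the metric curves of the cycles are averaged pointwise and the
    correction maximizing the average is fixed before the next mode is
    scanned. When the averaged curve is flat to within a small relative
    tolerance (an insensitive mode), the candidate closest to zero wins.
    Each metric evaluation is one coefficient transition, so
    transitions = n_modes * steps * cycles.

    ``n_passes`` splits the cycle budget over repeated sweeps of the whole
    mode sequence (cycles must divide evenly): each sweep re-scans every
    mode with cycles/n_passes metric curves and updates its correction in
    place. Large mixed aberrations couple modes (e.g. spherical aberration
    shifts the best defocus), so a single sweep settles on balanced rather
    than nulled coefficients; repeated sweeps converge to the null while
    spending exactly the same total number of coefficient transitions.
    """
    if steps % 2 == 0:
        raise ValueError("steps must be odd so that 0 is a tested grid point")
    if scan_range <= 0:
        raise ValueError("scan range must be positive")
    if n_modes is None:
        n_modes = true_aberration.n_modes
    true = np.zeros(n_modes)
    true[: true_aberration.n_modes] = true_aberration.coeffs[:n_modes]
    rng = np.random.default_rng(seed)
    basis = zernike_basis(n_modes, grid_px, start_noll=start_noll)
    scan_values = np.linspace(-scan_range, scan_range, steps)
    range_limited = bool(np.any(np.abs(true) > scan_range))

    def metric_for(coeffs: np.ndarray) -> float:
        pupil = make_pupil(ZernikeCoefficients(coeffs), grid_px, basis=basis)
        # unnormalized: the PSF total carries the excitation efficiency,
        # which is what the mean-intensity metric feeds on
        psf = two_photon_psf(pupil, pad_factor=pad_factor, normalize=False)
        _, m = simulate_image(sample, psf, noise_model, rng)
        return m

    if cycles % n_passes != 0:
        raise ValueError("cycles must be divisible by n_passes")
    cycles_per_pass = cycles // n_passes

    corrections = np.zeros(n_modes)
    trajectory: list[float] = []
    mode_scans: list[dict] = []
    initial_metric = metric_for(true)

    for p in range(n_passes):
        for k in range(n_modes):
            curves = np.zeros((cycles_per_pass, steps))
            for c in range(cycles_per_pass):
                for s, v in enumerate(scan_values):
                    test = corrections.copy()
                    test[k] = v
                    curves[c, s] = metric_for(true + test)
                    trajectory.append(curves[c, s])
            avg = curves.mean(axis=0)
            spread = avg.max() - avg.min()
            if spread <= 1e-6 * max(abs(avg.max()), 1e-300):
                best = 0.0  # metric flat in this mode: leave it uncorrected
            else:
                # among near-maximal candidates, prefer the smallest correction
                near = np.flatnonzero(avg >= avg.max() - 1e-9 * spread)
                best = scan_values[near[np.argmin(np.abs(scan_values[near]))]]
            corrections[k] = best
            mode_scans.append(
                {"mode_noll": k + start_noll, "pass": p,
                 "scan_values": scan_values.copy(),
                 "avg_metric": avg, "selected": float(best)}
            )

    final_metric = metric_for(true + corrections)
    return AoResult(
        corrections=ZernikeCoefficients(corrections),
        residual=ZernikeCoefficients(true + corrections),
        metric_trajectory=np.asarray(trajectory),
        transitions=n_modes * steps * cycles,
        mode_scans=mode_scans,
        initial_metric=initial_metric,
        final_metric=final_metric,
        range_limited=range_limited,
    )
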