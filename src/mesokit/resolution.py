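"""PSF resolution characterization from bead z-stacks, and analytic
system-geometry quantities.

Resolution is quantified as the FWHM of a least-squares Gaussian fit to the
x, y and z line profiles through each bead (FWHM = 2 sqrt(2 ln 2) sigma).
The field of view is sampled at a centre point plus three concentric rings
of eight positions each (45 degree spacing).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .core import VolumeStack

__all__ = [
    "FWHM_PER_SIGMA",
    "FovLayout",
    "fov_positions",
    "fit_fwhm",
    "GaussianFitError",
    "PsfFit",
    "characterize_stack",
    "system_geometry",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

RING_RADII_MM = (1.33, 2.66, 3.99)


@dataclass
class FovLayout:
    """Resolution-sampling layout: centre + three rings of eight positions."""

    positions: pd.DataFrame  # columns: label, radius_mm, angle_deg, x_mm, y_mm
    ring_radii_mm: tuple[float, ...] = RING_RADII_MM


def fov_positions(ring_radii_mm: tuple[float, ...] = RING_RADII_MM) -> FovLayout:
    """Centre point plus ``len(ring_radii_mm)`` rings sampled every 45 deg.

    With the default three rings this yields 25 positions (1 + 3 x 8),
    labelled A (centre) then B, C, D by increasing radius.
    """
    rows = [{"label": "A", "radius_mm": 0.0, "angle_deg": 0.0, "x_mm": 0.0, "y_mm": 0.0}]
    labels = [chr(ord("B") + i) for i in range(len(ring_radii_mm))]
    for label, radius in zip(labels, ring_radii_mm):
        for angle in range(0, 360, 45):
            rad = np.deg2rad(angle)
            rows.append(
                {
                    "label": label,
                    "radius_mm": radius,
                    "angle_deg": float(angle),
                    "x_mm": radius * np.cos(rad),
                    "y_mm": radius * np.sin(rad),
                }
            )
    return FovLayout(positions=pd.DataFrame(rows), ring_radii_mm=tuple(ring_radii_mm))


class GaussianFitError(RuntimeError):
    """Raised when a profile cannot be fit by a Gaussian (with diagnostics)."""

    def __init__(self, message: str, r_squared: float | None = None):
        self.r_squared = r_squared
        super().__init__(message)


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float, offset: float) -> np.ndarray:
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + offset


def fit_fwhm(
    profile: np.ndarray,
    spacing_um: float,
    min_r_squared: float = 0.5,
    return_fit: bool = False,
):
    """FWHM (um) of a Gaussian + constant-offset least-squares fit.

    The profile must show a single dominant peak sampled at ``spacing_um``.
    Raises GaussianFitError on non-convergence or R^2 below
    ``min_r_squared``.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    x = np.arange(len(y)) * float(spacing_um)
    offset0 = float(y.min())
    amp0 = float(y.max() - offset0)
    if amp0 <= 0:
        raise GaussianFitError("profile is flat; no peak to fit")
    mu0 = float(x[int(np.argmax(y))])
    above_half = y - offset0 > amp0 / 2
    sigma0 = max(above_half.sum() * spacing_um / FWHM_PER_SIGMA, spacing_um / 2)
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=[amp0, mu0, sigma0, offset0],
            bounds=([0, x.min() - spacing_um, 1e-9, -np.inf], [np.inf, x.max() + spacing_um, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise GaussianFitError(f"Gaussian fit did not converge: {exc}") from exc
    resid = y - _gaussian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r_squared:
        raise GaussianFitError(f"Gaussian fit R^2 = {r2:.3f} < {min_r_squared}", r_squared=r2)
    fwhm = float(FWHM_PER_SIGMA * popt[2])
    if return_fit:
        return fwhm, {"amp": popt[0], "mu_um": popt[1], "sigma_um": popt[2],
                      "offset": popt[3], "r_squared": r2}
    return fwhm


@dataclass
class PsfFit:
    """Per-bead three-axis FWHM fit."""

    position_voxel: tuple[int, int, int]
    fwhm_um: dict[str, float]  # keys 'z', 'y', 'x'
    r_squared: dict[str, float]
    profiles: dict[str, np.ndarray] = field(default_factory=dict)


def _detect_beads(data: np.ndarray, prominence: float) -> list[tuple[int, int, int]]:
    """Local maxima above ``prominence`` x the global peak, de-duplicated by a
    maximum filter over a small neighbourhood."""
    threshold = prominence * data.max()
    footprint = np.ones((5, 9, 9))
    local_max = (data == ndimage.maximum_filter(data, footprint=footprint)) & (data > threshold)
    return [tuple(int(v) for v in p) for p in np.argwhere(local_max)]


def _refined_peak(data: np.ndarray, voxel: tuple[int, int, int]) -> np.ndarray:
    """Quadratic sub-voxel refinement of a local maximum, per axis."""
    pos = np.array(voxel, dtype=float)
    for ax in range(3):
        idx = list(voxel)
        c = voxel[ax]
        if c == 0 or c == data.shape[ax] - 1:
            continue
        vals = []
        for d in (-1, 0, 1):
            idx[ax] = c + d
            vals.append(float(data[tuple(idx)]))
        idx[ax] = c
        denom = vals[0] - 2 * vals[1] + vals[2]
        if denom < 0:
            pos[ax] = c + 0.5 * (vals[0] - vals[2]) / denom
    return pos


def characterize_stack(
    stack: VolumeStack,
    bead_positions_voxel: list[tuple[int, int, int]] | None = None,
    prominence: float = 0.3,
    profile_halfwidth_fwhm: float = 3.0,
    border_fwhm: float = 3.0,
) -> tuple[list[PsfFit], pd.DataFrame]:
    """Fit per-axis FWHM for every bead in a z-stack.

    Beads are detected as local maxima above ``prominence`` x the global
    peak unless positions are supplied. For each bead, x/y/z line profiles
    are taken through the sub-voxel-refined peak and fit with
    :func:`fit_fwhm`. Beads whose profile window would cross the stack
    border are excluded from the summary. Returns the per-bead fits and a
    mean +- SD summary per axis.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("bead stack must be 3D (z, y, x)")
    spacing = stack.spacing_um
    if bead_positions_voxel is None:
        bead_positions_voxel = _detect_beads(data, prominence)
    if not bead_positions_voxel:
        raise ValueError("no beads detected in the stack")

    fits: list[PsfFit] = []
    axis_names = ("z", "y", "x")
    for voxel in bead_positions_voxel:
        refined = _refined_peak(data, voxel)
        center = tuple(int(round(v)) for v in refined)
        fwhm: dict[str, float] = {}
        r2: dict[str, float] = {}
        profiles: dict[str, np.ndarray] = {}
        ok = True
        for ax, name in enumerate(axis_names):
            idx: list = list(center)
            idx[ax] = slice(None)
            profile = data[tuple(idx)]
            try:
                w, info = fit_fwhm(profile, spacing[ax], return_fit=True)
            except GaussianFitError:
                ok = False
                break
            # border exclusion: peak must sit > border_fwhm * FWHM from edges
            margin = border_fwhm * w
            extent = (len(profile) - 1) * spacing[ax]
            if info["mu_um"] < margin or info["mu_um"] > extent - margin:
                ok = False
                break
            fwhm[name] = w
            r2[name] = info["r_squared"]
            profiles[name] = profile
        if ok:
            fits.append(PsfFit(position_voxel=center, fwhm_um=fwhm, r_squared=r2,
                               profiles=profiles))
    if not fits:
        raise ValueError("no bead produced a valid three-axis Gaussian fit")

    rows = []
    for name in axis_names:
        vals = np.array([f.fwhm_um[name] for f in fits])
        rows.append({"axis": name, "mean_fwhm_um": vals.mean(),
                     "sd_fwhm_um": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "n": len(vals)})
    return fits, pd.DataFrame(rows)


def system_geometry(
    fov_diameter_mm: float = 8.0,
    depth_mm: float = 0.9,
    lateral_res_um: float = 1.0,
) -> dict[str, float]:
    """Analytic imaging-geometry figures of merit.

    area = pi (d/2)^2 [mm^2]; volume = area x depth [mm^3];
    spatial bandwidth product = area in um^2 / (lateral resolution)^2.
    Rounded companions are emitted at conventional reporting precision
    (2 decimals for area/volume, 3 significant figures for SBP).
    """
    if fov_diameter_mm <= 0 or depth_mm <= 0 or lateral_res_um <= 0:
        raise ValueError("all geometry inputs must be positive")
    area_mm2 = np.pi * (fov_diameter_mm / 2.0) ** 2
    volume_mm3 = area_mm2 * depth_mm
    sbp = area_mm2 * 1e6 / lateral_res_um**2
    sbp_3sf = float(f"{sbp:.3g}")
    return {
        "area_mm2": float(area_mm2),
        "volume_mm3": float(volume_mm3),
        "sbp": float(sbp),
        "area_mm2_rounded": round(float(area_mm2), 2),
        "volume_mm3_rounded": round(float(volume_mm3), 2),
        "sbp_3sf": sbp_3sf,
    }
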