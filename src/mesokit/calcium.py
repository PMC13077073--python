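"""ROI fluorescence to dF/F, SNR, and Pearson correlation structure.

Conventions: f is a neurons x frames matrix of ROI-mean fluorescence; the
baseline f0 is the 15th percentile of each neuron's entire recording
(linear interpolation between order statistics); dF/F = (f - f0) / f0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DffTraces, FluorescenceTraces, VolumeStack

__all__ = [
    "extract_traces",
    "subtract_neuropil",
    "compute_dff",
    "compute_snr",
    "SnrResult",
    "correlation_matrix",
    "correlation_vs_distance",
    "count_pairs",
]

logger = logging.getLogger(__name__)


def extract_traces(
    movie: VolumeStack,
    roi_masks: np.ndarray,
    frame_rate_hz: float | None = None,
    annulus_um: tuple[float, float] = (8.0, 20.0),
    positions_um: np.ndarray | None = None,
    region_labels: list[str] | None = None,
) -> FluorescenceTraces:
    """Average pixel values inside each ROI per frame; neuropil from an
    annulus around the ROI excluding all ROIs.

    ``movie.data`` is (frames, y, x); ``roi_masks`` is (n_rois, y, x)
    boolean. The neuropil annulus spans ``annulus_um`` (inner, outer)
    physical distance from the ROI boundary.
    """
    data = movie.data
    if data.ndim != 3:
        raise ValueError("movie must be (frames, y, x)")
    masks = np.asarray(roi_masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[1:] != data.shape[1:]:
        raise ValueError("roi_masks must be (n_rois, y, x) matching the movie frame")
    n_rois, n_frames = masks.shape[0], data.shape[0]
    pixel_um = float(movie.spacing_um[-1])

    flat = data.reshape(n_frames, -1)
    any_roi = masks.any(axis=0)
    f = np.empty((n_rois, n_frames))
    f_np = np.empty((n_rois, n_frames))
    for i in range(n_rois):
        m = masks[i]
        if not m.any():
            raise ValueError(f"ROI {i} is empty")
        f[i] = flat[:, m.ravel()].mean(axis=1)
        inner_px = max(1, int(round(annulus_um[0] / pixel_um)))
        outer_px = max(inner_px + 1, int(round(annulus_um[1] / pixel_um)))
        dil_inner = ndimage.binary_dilation(m, iterations=inner_px)
        dil_outer = ndimage.binary_dilation(m, iterations=outer_px)
        annulus = dil_outer & ~dil_inner & ~any_roi
        if not annulus.any():
            annulus = ~any_roi  # tiny frames: fall back to all non-ROI pixels
        f_np[i] = flat[:, annulus.ravel()].mean(axis=1)

    return FluorescenceTraces(
        f=f,
        f_neuropil=f_np,
        frame_rate_hz=frame_rate_hz or 1.0,
        positions_um=positions_um,
        region_labels=region_labels,
    )


def subtract_neuropil(
    traces: FluorescenceTraces, coeff: float, floor: float = 1e-6
) -> FluorescenceTraces:
    """f_corrected = f - coeff * f_neuropil, floored to stay positive.

    If the subtraction drives any value below ``floor`` a constant offset is
    added to the whole matrix and recorded in ``neuropil_offset``, so the
    baseline percentile stays strictly positive for dF/F.
    """
    if not (0 <= coeff < 1):
        raise ValueError("neuropil coefficient must lie in [0, 1)")
    if traces.f_neuropil is None:
        raise ValueError("traces carry no neuropil component to subtract")
    corrected = traces.f - coeff * traces.f_neuropil
    offset = 0.0
    lowest = corrected.min()
    if lowest < floor:
        offset = floor - lowest
        corrected = corrected + offset
        logger.info("neuropil subtraction offset +%.4g applied to keep traces positive", offset)
    return FluorescenceTraces(
        f=corrected,
        f_neuropil=traces.f_neuropil,
        frame_rate_hz=traces.frame_rate_hz,
        positions_um=traces.positions_um,
        region_labels=traces.region_labels,
        neuropil_offset=offset,
    )


def compute_dff(traces: FluorescenceTraces, percentile: float = 15.0) -> DffTraces:
    """dF/F with the per-neuron baseline f0 = the given percentile of the
    entire recording (default 15th, linear interpolation)."""
    f0 = np.percentile(traces.f, percentile, axis=1, method="linear")
    bad = np.where(f0 <= 0)[0]
    if bad.size:
        raise ValueError(
            f"baseline f0 <= 0 for neurons {bad.tolist()} "
            "(possible neuropil over-subtraction)"
        )
    dff = (traces.f - f0[:, None]) / f0[:, None]
    return DffTraces(
        dff=dff,
        f0=f0,
        frame_rate_hz=traces.frame_rate_hz,
        positions_um=traces.positions_um,
        region_labels=traces.region_labels,
    )


@dataclass
class SnrResult:
    snr: np.ndarray  # per neuron; 0 where no transients detected
    no_transients: np.ndarray  # boolean flag per neuron
    n_transients: np.ndarray


def compute_snr(
    dff: DffTraces, k_mad: float = 3.0, min_duration_frames: int = 2
) -> SnrResult:
    """Transient-based signal-to-noise ratio.

    A transient is a run of >= ``min_duration_frames`` consecutive frames
    exceeding median + k * 1.4826 * MAD of the trace. SNR = mean transient
    peak amplitude (above the median) divided by the SD of the trace with
    transient frames removed. Neurons with no detected transient get SNR 0
    and a flag.
    """
    if dff.n_frames < 100:
        raise ValueError("SNR estimation needs at least 100 frames")
    n = dff.n_neurons
    snr = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        x = dff.dff[i]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        if mad == 0:
            mad = x.std() or 1.0
        above = x > med + k_mad * mad
        runs = _runs(above)
        runs = [(s, e) for s, e in runs if e - s >= min_duration_frames]
        if not runs:
            flags[i] = True
            continue
        counts[i] = len(runs)
        peaks = [x[s:e].max() - med for s, e in runs]
        keep = ~above
        noise_sd = x[keep].std() if keep.sum() >= 2 else x.std()
        snr[i] = float(np.mean(peaks) / noise_sd) if noise_sd > 0 else 0.0
    return SnrResult(snr=snr, no_transients=flags, n_transients=counts)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list(zip(starts, ends))


def correlation_matrix(
    dff: DffTraces, frame_mask: np.ndarray | None = None, min_frames: int = 30
) -> np.ndarray:
    """Pairwise Pearson correlation over the selected frames.

    Zero-variance traces get NaN rows/columns (excluded downstream rather
    than forced to 0); the diagonal is 1 for valid neurons.
    """
    x = dff.dff
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if frame_mask.sum() < min_frames:
            raise ValueError(
                f"frame mask selects {int(frame_mask.sum())} frames; need >= {min_frames}"
            )
        x = x[:, frame_mask]
    elif x.shape[1] < min_frames:
        raise ValueError(f"recording has {x.shape[1]} frames; need >= {min_frames}")
    sd = x.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("excluding %d zero-variance traces from correlation", int(zero_var.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, np.where(zero_var, np.nan, 1.0))
    return corr


def correlation_vs_distance(
    corr: np.ndarray,
    positions_um: np.ndarray,
    bin_width_um: float = 50.0,
) -> "pd.DataFrame":
    """Binned profile of pairwise correlation vs inter-neuron distance.

    Bins are [k*w, (k+1)*w); the table has one row per bin up to the largest
    pair distance, with mean, SD and count (empty bins have count 0). NaN
    correlations (excluded neurons) are skipped.
    """
    import pandas as pd

    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    positions = np.asarray(positions_um, dtype=float)
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[iu[0]] - positions[iu[1]], axis=1)
    r = corr[iu]
    valid = np.isfinite(r)
    d, r = d[valid], r[valid]
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1 if len(d) else 1
    idx = np.minimum((d / bin_width_um).astype(int), n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = r[idx == k]
        rows.append(
            {
                "bin_low_um": k * bin_width_um,
                "bin_high_um": (k + 1) * bin_width_um,
                "mean_r": sel.mean() if len(sel) else np.nan,
                "sd_r": sel.std(ddof=1) if len(sel) > 1 else np.nan,
                "n_pairs": len(sel),
            }
        )
    return pd.DataFrame(rows)


def count_pairs(n: int) -> int:
    """Number of unordered neuron pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 neurons for pairs")
    return n * (n - 1) // 2
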