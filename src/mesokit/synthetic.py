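"""Synthetic data generators with known ground truth.

Every generator is a pure function of its spec and an integer seed: the same
inputs reproduce bit-identical output. Four families of fixtures are
produced, each emulating one of the experimental data types of a mesoscale
two-photon study:

* tubular vascular phantoms with exact centerline/radius ground truth,
* calcium movies/traces with region-structured correlations whose shared
  drive is amplified during locomotion ("moving") epochs,
* sub-resolution fluorescent bead stacks imaged through a Gaussian PSF,
* sparse structured ("pollen-like") samples for adaptive-optics simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    CenterlineGraph,
    CenterlineSegment,
    LocomotionTrace,
    VolumeStack,
    ZernikeCoefficients,
)

__all__ = [
    "PhantomSpec",
    "CalciumSceneSpec",
    "GroundTruth",
    "INDICATOR_KINETICS",
    "indicator_kernel",
    "generate_vascular_phantom",
    "generate_locomotion",
    "generate_calcium_traces",
    "generate_calcium_movie",
    "generate_bead_stack",
    "generate_ao_sample",
]

#: Rise/decay time constants (seconds) of the difference-of-exponentials
#: calcium indicator kernels. Values are conventional for the two indicators;
#: override per call if needed.
INDICATOR_KINETICS = {
    "GCaMP6s": {"rise_s": 0.18, "decay_s": 1.5},
    "GCaMP6f": {"rise_s": 0.08, "decay_s": 0.4},
}


# ---------------------------------------------------------------------------
# vascular phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and intensity model of a tubular vascular phantom.

    ``segments`` is a list of straight tubes, each a tuple
    ``(start_um, end_um, radius_um)`` with endpoints in (z, y, x)
    micrometres. The default grid emulates a 1000 x 1000 um field sampled at
    600 x 600 pixels with a 10 um z step, scaled down for desk-sized tests.
    """

    shape_voxels: tuple[int, int, int]
    spacing_um: tuple[float, float, float]
    segments: list[tuple[tuple[float, float, float], tuple[float, float, float], float]]
    background_intensity: float = 0.05
    vessel_intensity: float = 1.0
    noise_sd: float = 0.0
    psf_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing components must be positive")
        if any(r <= 0 for _, _, r in self.segments):
            raise ValueError("all tube radii must be positive")
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")


@dataclass
class GroundTruth:
    """Exact ground truth emitted alongside every generated dataset."""

    centerlines: Optional[CenterlineGraph] = None
    vessel_mask: Optional[np.ndarray] = None
    roi_masks: Optional[np.ndarray] = None
    spike_trains: Optional[np.ndarray] = None
    clean_dff: Optional[np.ndarray] = None
    state_mask: Optional[np.ndarray] = None
    positions_um: Optional[np.ndarray] = None
    region_labels: Optional[list[str]] = None
    true_psf_fwhm_um: Optional[tuple[float, float, float]] = None
    bead_fwhm_um: Optional[tuple[float, float, float]] = None
    observed_fwhm_um: Optional[tuple[float, float, float]] = None
    bead_positions_um: Optional[np.ndarray] = None
    true_zernike: Optional[ZernikeCoefficients] = None
    warnings: list[str] = field(default_factory=list)


def _rasterize_tube(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    start: np.ndarray,
    end: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the finite cylinder
    around the start-end axis (perpendicular foot within the segment, no
    spherical end caps, so the voxel count converges to the analytic
    cylinder volume). Only the tube's bounding box is evaluated."""
    lo_um = np.minimum(start, end) - radius
    hi_um = np.maximum(start, end) + radius
    lo = np.maximum(np.floor(lo_um / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / spacing).astype(int) + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(
        *[np.arange(a, b) * s for a, b, s in zip(lo, hi, spacing)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)  # (n_vox, 3) um
    d = end - start
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - start, axis=1)
        inside = dist <= radius
    else:
        t = (pts - start) @ d / seg_len2
        proj = start + t[:, None] * d
        dist = np.linalg.norm(pts - proj, axis=1)
        inside = (dist <= radius) & (t >= 0.0) & (t <= 1.0)
    box = inside.reshape(tuple(hi - lo))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = box
    return mask


def generate_vascular_phantom(
    spec: PhantomSpec, seed: int = 0
) -> tuple[VolumeStack, GroundTruth]:
    """Rasterize a tube phantom with exact centerline ground truth.

    A voxel is foreground iff its centre lies within a tube radius of a tube
    axis. The intensity image is the mask scaled between background and
    vessel intensity, optionally blurred by a small Gaussian PSF, with
    additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape_voxels)
    spacing = tuple(spec.spacing_um)
    mask = np.zeros(shape, dtype=bool)
    warnings: list[str] = []
    segments: list[CenterlineSegment] = []
    step = min(spacing)
    for i, (start, end, radius) in enumerate(spec.segments):
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        mask |= _rasterize_tube(shape, spacing, start, end, radius)
        if radius < max(spacing) / 2:
            warnings.append(
                f"segment {i}: radius {radius} um is below half the largest "
                f"voxel spacing ({max(spacing)} um); tube may be unresolvable"
            )
        length = float(np.linalg.norm(end - start))
        n_pts = max(2, int(np.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n_pts)
        pts = start[None, :] + t[:, None] * (end - start)[None, :]
        segments.append(
            CenterlineSegment(
                segment_id=i,
                points_um=pts,
                radii_um=np.full(n_pts, radius),
            )
        )

    image = np.where(mask, spec.vessel_intensity, spec.background_intensity).astype(float)
    if any(s > 0 for s in spec.psf_sigma_um):
        sigma_vox = [s / sp for s, sp in zip(spec.psf_sigma_um, spacing)]
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    truth = GroundTruth(
        centerlines=CenterlineGraph(segments=segments, spacing_um=spacing),
        vessel_mask=mask,
        warnings=warnings,
    )
    return VolumeStack(data=image, spacing_um=spacing), truth


# ---------------------------------------------------------------------------
# locomotion and calcium
# ---------------------------------------------------------------------------

def generate_locomotion(
    n_frames: int,
    frame_rate_hz: float,
    stationary_fraction: float = 0.7,
    stationary_speed_mm_s: float = 1.2,
    moving_speed_mm_s: float = 80.0,
    mean_bout_s: float = 20.0,
    seed: int = 0,
) -> tuple[LocomotionTrace, np.ndarray]:
    """Two-state semi-Markov locomotion trace.

    Epoch durations are exponential with state-dependent means chosen so the
    expected occupancy matches ``stationary_fraction``. Stationary speeds
    hover near ~1 mm/s, moving speeds near 70-90 mm/s, mimicking the two
    regimes seen on an air-floating platform. Returns the speed trace and the
    boolean moving mask (True = moving).
    """
    rng = np.random.default_rng(seed)
    mean_stat = 2 * mean_bout_s * stationary_fraction
    mean_move = 2 * mean_bout_s * (1 - stationary_fraction)
    state = rng.random() > stationary_fraction  # True = moving
    moving = np.zeros(n_frames, dtype=bool)
    t = 0
    while t < n_frames:
        mean_dur = mean_move if state else mean_stat
        dur = max(1, int(round(rng.exponential(mean_dur) * frame_rate_hz)))
        moving[t : t + dur] = state
        t += dur
        state = not state
    speed = np.where(
        moving,
        np.clip(rng.normal(moving_speed_mm_s, moving_speed_mm_s * 0.4, n_frames), 20.0, None),
        np.abs(rng.normal(stationary_speed_mm_s, stationary_speed_mm_s, n_frames)),
    )
    return LocomotionTrace(speed_mm_s=speed, frame_rate_hz=frame_rate_hz), moving


def indicator_kernel(
    frame_rate_hz: float,
    rise_s: float,
    decay_s: float,
    duration_s: float | None = None,
) -> np.ndarray:
    """Difference-of-exponentials calcium indicator kernel, peak-normalized.

    k(t) = exp(-t/decay) - exp(-t/rise), scaled to unit peak; sampled at the
    frame interval out to ~6 decay constants.
    """
    if duration_s is None:
        duration_s = 6 * decay_s
    t = np.arange(0, duration_s, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: rise must be shorter than decay")
    return k / peak


@dataclass
class CalciumSceneSpec:
    """Statistical model of a population calcium recording.

    Neurons are split evenly across ``n_regions`` regions placed at
    ``region_centers_um`` (y, x). Spikes are inhomogeneous Poisson driven by
    a private process plus region-shared and global latent drives; the
    shared-drive amplitude is multiplied by ``moving_gain`` during moving
    frames. Pairwise latent correlation is ``intra_region_coupling`` within a
    region and ``inter_region_coupling`` across regions.
    """

    n_neurons: int = 60
    n_regions: int = 3
    region_centers_um: Optional[list[tuple[float, float]]] = None
    region_spread_um: float = 150.0
    frame_rate_hz: float = 7.0
    duration_s: float = 600.0
    indicator: str = "GCaMP6s"
    base_rate_hz: float = 0.2
    moving_gain: float = 3.0
    intra_region_coupling: float = 0.8
    inter_region_coupling: float = 0.1
    neuropil_coeff: float = 0.7
    noise_sd: float = 0.05
    transient_amplitude: float = 1.0
    drive_strength: float = 1.0
    stationary_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.intra_region_coupling >= self.inter_region_coupling >= 0):
            raise ValueError("need intra_region_coupling >= inter_region_coupling >= 0")
        if self.intra_region_coupling > 1:
            raise ValueError("couplings must lie in [0, 1]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not (0 <= self.neuropil_coeff < 1):
            raise ValueError("neuropil_coeff must lie in [0, 1)")
        if self.indicator not in INDICATOR_KINETICS:
            raise ValueError(f"unknown indicator {self.indicator!r}")


def _smooth_unit_noise(rng: np.random.Generator, n: int, sigma_frames: float) -> np.ndarray:
    """Gaussian-smoothed standard-normal process re-standardized to unit SD."""
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma_frames, mode="wrap")
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_calcium_traces(
    spec: CalciumSceneSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth, LocomotionTrace]:
    """Generate ROI fluorescence traces (and neuropil) without rasterizing.

    Returns ``(f, f_neuropil, truth, locomotion)`` where ``f`` is
    neurons x frames raw fluorescence including neuropil contamination and
    noise. The coupling model: latent for neuron i of region r is

        x_i = sqrt(c_inter) g0 + sqrt(c_intra - c_inter) g_r + sqrt(1 - c_intra) z_i

    giving latent correlation c_intra within and c_inter across regions; the
    shared part (g0, g_r contributions) is multiplied by ``moving_gain``
    during moving frames. Spike rate is the rectified linear modulation
    base_rate * max(0, 1 + drive_strength * x_i); spikes are Poisson per
    frame and convolved with the indicator kernel. The linear link keeps
    count correlations ordered like the latent correlations even when the
    moving gain inflates the shared variance (a log link would collapse
    weak couplings at high gain).
    """
    kin = INDICATOR_KINETICS[spec.indicator]
    if spec.duration_s < kin["decay_s"]:
        raise ValueError(
            f"duration {spec.duration_s}s is shorter than the indicator decay "
            f"constant {kin['decay_s']}s"
        )
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    dt = 1.0 / spec.frame_rate_hz
    n = spec.n_neurons
    regions = np.arange(n) % spec.n_regions

    locomotion, moving = generate_locomotion(
        n_frames,
        spec.frame_rate_hz,
        stationary_fraction=spec.stationary_fraction,
        seed=spec.seed + 1,
    )
    gain = np.where(moving, spec.moving_gain, 1.0)

    # latent drives, smoothed over ~0.3 s
    sig_frames = max(1.0, 0.3 * spec.frame_rate_hz)
    g0 = _smooth_unit_noise(rng, n_frames, sig_frames)
    g_region = np.stack(
        [_smooth_unit_noise(rng, n_frames, sig_frames) for _ in range(spec.n_regions)]
    )
    w_inter = np.sqrt(spec.inter_region_coupling)
    w_intra = np.sqrt(spec.intra_region_coupling - spec.inter_region_coupling)
    w_priv = np.sqrt(1.0 - spec.intra_region_coupling)

    kernel = indicator_kernel(spec.frame_rate_hz, kin["rise_s"], kin["decay_s"])
    spikes = np.zeros((n, n_frames))
    clean_dff = np.zeros((n, n_frames))
    for i in range(n):
        z = _smooth_unit_noise(rng, n_frames, sig_frames)
        shared = w_inter * g0 + w_intra * g_region[regions[i]]
        latent = spec.drive_strength * (gain * shared + w_priv * z)
        rate = spec.base_rate_hz * np.clip(1.0 + latent, 0.0, None)
        spikes[i] = rng.poisson(rate * dt)
        conv = np.convolve(spikes[i], kernel)[:n_frames]
        clean_dff[i] = spec.transient_amplitude * conv

    # ROI centroids scattered around region centers
    if spec.region_centers_um is None:
        centers = np.array(
            [[0.0, 1000.0 * r] for r in range(spec.n_regions)]
        )
    else:
        centers = np.asarray(spec.region_centers_um, dtype=float)
    positions = centers[regions] + rng.normal(0, spec.region_spread_um, size=(n, 2))

    baseline_f = 1.0
    somatic = baseline_f * (1.0 + clean_dff)
    # neuropil: low-pass-filtered average of all somatic signals
    neuropil = ndimage.gaussian_filter1d(somatic.mean(axis=0), 2 * sig_frames, mode="nearest")
    f_neuropil = np.tile(neuropil, (n, 1))
    f = somatic + spec.neuropil_coeff * f_neuropil
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)

    truth = GroundTruth(
        spike_trains=spikes,
        clean_dff=clean_dff,
        state_mask=moving,
        positions_um=positions,
        region_labels=[f"region_{r}" for r in regions],
    )
    return f, f_neuropil, truth, locomotion


def generate_calcium_movie(
    spec: CalciumSceneSpec,
    pixel_size_um: float = 4.0,
    roi_radius_um: float = 6.0,
) -> tuple[VolumeStack, GroundTruth, LocomotionTrace]:
    """Render a calcium movie (frames, y, x) from the trace-level model.

    Each neuron is a uniform disk ROI whose pixels carry the somatic
    fluorescence (including neuropil contamination); pixel noise is added on
    top. Ground truth carries per-neuron boolean ROI masks, spike trains,
    clean dF/F and the moving-state mask.
    """
    f, f_neuropil, truth, locomotion = generate_calcium_traces(spec)
    rng = np.random.default_rng(spec.seed + 2)
    pos = truth.positions_um
    margin = 3 * roi_radius_um
    ymin, xmin = pos.min(axis=0) - margin
    ymax, xmax = pos.max(axis=0) + margin
    ny = int(np.ceil((ymax - ymin) / pixel_size_um)) + 1
    nx = int(np.ceil((xmax - xmin) / pixel_size_um)) + 1
    n_frames = f.shape[1]

    yy, xx = np.meshgrid(
        ymin + np.arange(ny) * pixel_size_um,
        xmin + np.arange(nx) * pixel_size_um,
        indexing="ij",
    )
    masks = np.zeros((spec.n_neurons, ny, nx), dtype=bool)
    for i in range(spec.n_neurons):
        d2 = (yy - pos[i, 0]) ** 2 + (xx - pos[i, 1]) ** 2
        masks[i] = d2 <= roi_radius_um**2
    # drop overlap pixels from both ROIs so ROI means stay exact
    overlap = masks.sum(axis=0) > 1
    masks &= ~overlap[None, :, :]

    movie = np.zeros((n_frames, ny, nx))
    for i in range(spec.n_neurons):
        movie[:, masks[i]] = f[i][:, None]
    # neuropil fills the background (already included in f inside ROIs)
    background = spec.neuropil_coeff * f_neuropil[0]
    outside = ~masks.any(axis=0)
    movie[:, outside] = background[:, None]
    if spec.noise_sd > 0:
        movie = movie + rng.normal(0.0, spec.noise_sd, size=movie.shape)

    truth.roi_masks = masks
    stack = VolumeStack(data=movie, spacing_um=(pixel_size_um, pixel_size_um))
    return stack, truth, locomotion


# ---------------------------------------------------------------------------
# bead stacks
# ---------------------------------------------------------------------------

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def generate_bead_stack(
    psf_fwhm_um: tuple[float, float, float],
    bead_fwhm_um: tuple[float, float, float],
    positions_um: Sequence[tuple[float, float, float]],
    spacing_um: tuple[float, float, float] = (0.27, 0.056, 0.056),
    shape_voxels: Optional[tuple[int, int, int]] = None,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[VolumeStack, GroundTruth]:
    """Synthesize a z-stack of Gaussian beads imaged through a Gaussian PSF.

    Both the bead and the PSF are Gaussian, so the imaged blob is their
    closed-form convolution: per axis,
    FWHM_obs = sqrt(FWHM_psf^2 + FWHM_bead^2). The default z step is 0.27 um,
    matching a motorized-stage axial scan; lateral pitch ~0.056 um.
    """
    positions = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    psf = np.asarray(psf_fwhm_um, dtype=float)
    bead = np.asarray(bead_fwhm_um, dtype=float)
    obs_fwhm = np.sqrt(psf**2 + bead**2)
    if np.any(obs_fwhm <= 0):
        raise ValueError("observed FWHM must be positive on every axis")
    sigma = obs_fwhm / _FWHM_PER_SIGMA
    spacing = np.asarray(spacing_um, dtype=float)
    if shape_voxels is None:
        margin = 5 * obs_fwhm
        extent = positions.max(axis=0) + margin
        shape_voxels = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spacing))

    warnings: list[str] = []
    if len(positions) > 1:
        from scipy.spatial.distance import pdist

        if pdist(positions).min() < 5 * obs_fwhm.max():
            warnings.append("beads closer than 5x max FWHM: blobs may overlap")

    axes = [np.arange(n) * s for n, s in zip(shape_voxels, spacing)]
    stack = np.zeros(shape_voxels)
    for p in positions:
        profs = [
            np.exp(-((ax - c) ** 2) / (2 * sg**2))
            for ax, c, sg in zip(axes, p, sigma)
        ]
        stack += amplitude * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)

    truth = GroundTruth(
        true_psf_fwhm_um=tuple(psf),
        bead_fwhm_um=tuple(bead),
        observed_fwhm_um=tuple(obs_fwhm),
        bead_positions_um=positions,
        warnings=warnings,
    )
    return VolumeStack(data=stack, spacing_um=tuple(spacing)), truth


# ---------------------------------------------------------------------------
# adaptive-optics samples
# ---------------------------------------------------------------------------

def generate_ao_sample(
    size_px: int = 128,
    n_grains: int = 8,
    grain_radius_px: float = 6.0,
    seed: int = 0,
    centered: bool = False,
) -> np.ndarray:
    """Sparse bright textured blobs on a dark background, normalized to [0, 1].

    Emulates a pollen-grain calibration slide: high-contrast sparse
    structure, which is what makes mean fluorescence intensity a usable
    aberration metric (a uniform sample would be insensitive to PSF width).
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1 (uniform sample degenerates the metric)")
    rng = np.random.default_rng(seed)
    img = np.zeros((size_px, size_px))
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    if centered and n_grains == 1:
        centers = np.array([[size_px / 2, size_px / 2]])
    else:
        lo, hi = 0.15 * size_px, 0.85 * size_px
        centers = rng.uniform(lo, hi, size=(n_grains, 2))
    for cy, cx in centers:
        r = grain_radius_px * rng.uniform(0.7, 1.3)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += np.exp(-(d2 / (2 * (r / 1.5) ** 2)) ** 2)  # super-Gaussian disk
    texture = 1.0 + 0.3 * ndimage.gaussian_filter(rng.standard_normal(img.shape), 1.5)
    img *= np.clip(texture, 0.2, None)
    img -= img.min()
    peak = img.max()
    if peak > 0:
        img /= peak
    return img
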