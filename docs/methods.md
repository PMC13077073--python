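# Methods

This note documents the models, numerical choices and limitations behind
each mesokit module. Problem sizes quoted here are the defaults the test
suite and `scripts/acceptance.py` use.

## Synthetic data model

The generators stand in for in vivo recordings; they reproduce the
statistical structure the analyses depend on, with exact ground truth, and
deliberately omit everything else.

**Vascular phantoms.** Vessels are unions of straight finite cylinders
(curved vessels are polylines of short cylinders). A voxel is foreground
iff its centre lies within the tube radius of the axis with its
perpendicular foot inside the segment — no spherical end caps — so the
voxel count converges to the analytic cylinder volume π r² L as spacing
shrinks. Intensities are two-level (background/vessel) with optional
Gaussian PSF blur and additive Gaussian noise. Default grids emulate a
1000 × 1000 µm field at 600 × 600 px with a 10 µm z-step, scaled to
desk-sized test volumes (≤ 100³ voxels at 1–2 µm isotropic). Ground truth
carries the exact axes and radii; radii below half the largest voxel
spacing are flagged unresolvable.

**Calcium scenes.** Neuron `i` of region `r` has latent drive

    x_i = √c_inter · g₀ + √(c_intra − c_inter) · g_r + √(1 − c_intra) · z_i

with g₀ (global), g_r (region) and z_i (private) independent smoothed unit
Gaussian processes (≈0.3 s correlation time), giving latent correlation
`c_intra` within and `c_inter` across regions (defaults 0.8 / 0.1).
During "moving" frames the shared part is multiplied by `moving_gain`
(default 3). Spike rates use a rectified linear link,
`λ = λ₀ · max(0, 1 + x)` (λ₀ = 0.2 Hz): a log link would collapse weak
couplings at high gain because log-normal correlation saturates in the
variance. Poisson spike counts are convolved with a peak-normalized
difference-of-exponentials indicator kernel (GCaMP6s 0.18 s rise / 1.5 s
decay; GCaMP6f 0.08 s / 0.4 s — conventional values, overridable; the
kernel choice is a modelling decision, not a measured calibration).
Neuropil is a low-pass-filtered population-average signal added at a
contamination coefficient (default 0.7, the same value the analysis
subtracts — the round-trip is exact by construction, which the
contamination-recovery test exploits). Locomotion is a two-state
semi-Markov process (exponential bout durations, mean 20 s occupancy-
weighted; stationary speeds ≈1 mm/s, moving ≈70–90 mm/s) targeting a 70/30
stationary/moving split. What the model does **not** contain: distance-
dependent coupling inside a region, rate adaptation, photobleaching, slow
drift, or movement artefacts; passing tests therefore show the analysis
chain is correct, not that it is robust to those real-data effects.

**Bead stacks.** Both bead and PSF are Gaussian, so the imaged blob is the
closed-form convolution with per-axis
`FWHM_obs = √(FWHM_PSF² + FWHM_bead²)`; blobs are rasterized analytically
(no numerical convolution). Default spacing 0.27 µm axially and 0.056 µm
laterally, matching a motorized axial scan over a camera-calibrated
lateral grid. Generator settings of (10.88, 1.05, 1.05) µm emulate the
instrument-scale anisotropy (axial ≈ 10× lateral at NA 0.5); they are
inputs, not measurements.

**AO samples.** Sparse super-Gaussian "grains" with multiplicative
texture, normalized to [0, 1]. Sparse high-contrast structure is what
makes mean intensity a usable metric; a uniform sample is degenerate
(convolution with a unit-sum PSF preserves its mean), which is tested as
such.

## Vascular morphometry

Preprocessing steps are individually switchable and applied in a fixed
order: per-slice CLAHE, min–max normalization (a constant stack maps to
zeros), per-slice lateral Gaussian denoising, and per-slice rigid
translation registration to the median slice (phase correlation on
demeaned, Hann-windowed slices — the plain normalized variant locks onto
DC/edge artefacts on smooth slices). Crosstalk and dura removal are
documented no-ops: they need multichannel or surface data the fixtures do
not carry.

Segmentation is Otsu or fixed thresholding with small-object removal —
deliberately classical; CNN segmentation is out of scope and ground-truth
masks are available from the generator.

Centerlines: 3D topological skeletonization, branch voxels identified by a
topological criterion (a skeleton voxel is a branch iff its skeleton
neighbours fall into ≥3 connected components once it is removed — a plain
≥3-neighbour count misfires on diagonal staircase corners). Segments are
the non-branch components, ordered as the shortest weighted path between
the two most graph-distant voxels; stored coordinates are smoothed with a
5-point moving average (endpoints pinned) because the raw discrete path
overestimates curved arc length by 10–20 % through lattice zig-zag.
Radii are sampled from the anisotropic Euclidean distance transform
(physical µm — at a 10:1 z anisotropy voxel-unit distances would be
badly wrong), taking the local 3×3×3 maximum because the discrete
skeleton sits up to ~0.7 voxel off the medial ridge. Segments shorter
than 3 skeleton voxels are dropped as spurs (configurable, logged).
Single-voxel masks yield a flagged degenerate one-point segment.

Metrics follow the definitions in the README. IVD is midpoint-to-midpoint
(midpoint = centreline point at half arc length); a point-wise variant
(midpoint to any centreline point of another segment) is available behind
a flag but is not the default. With fewer than two segments IVD is NaN
("not applicable"). Box summaries use exclusive-median quartiles
([1..5] → Q1 1.5, Q3 4.5) and 1.5 × IQR whiskers.

Measured discretization behaviour on analytic phantoms (1–2 µm grids):
diameter within one voxel of 2 r, length within 3 % of the analytic arc
length between the skeleton's end planes (the skeleton erodes ~one radius
from free tube ends, so end-to-end comparisons use the skeleton's own
extent), density within 5 % for radii ≥ 2.5 voxels, all improving with
finer grids.

## Calcium and network analysis

ΔF/F uses the 15th percentile of each neuron's entire recording as f₀
(linear interpolation between order statistics); f₀ ≤ 0 is an error
pointing at neuropil over-subtraction, and the subtraction itself floors
traces by adding a recorded constant offset when needed. ΔF/F is invariant
to per-neuron gain by construction.

SNR has no canonical definition; the implemented contract is: transients
are runs of ≥2 frames above median + 3 × 1.4826 × MAD, and
SNR = (mean transient peak above median) / (SD of non-transient frames).
Both k and the run length are configurable. Reported in vivo SNR values
from any instrument are not comparable targets for this statistic.

Correlation matrices are Pearson r over selected frames (≥30 required);
zero-variance traces get NaN rows rather than r = 0 so they cannot bias
graph metrics. Connectivity edges require **signed** r strictly greater
than the threshold (0.3 for state comparisons); |r| mode exists behind a
flag. Degree and clustering (unweighted triangle ratio) are computed on
the binarized graph at 0.1 via NetworkX; strength sums suprathreshold
weights. Locomotion classification: 0.5 s boxcar smoothing, 10 mm/s
threshold, bouts shorter than 0.5 s merged (shortest first) — these
defaults separate the two synthetic speed regimes and are configuration,
not measured values. State comparisons require ≥30 frames per state and
threshold both states identically. Note a sampling caveat the null test
accounts for: with unequal frame counts the smaller state's r estimates
are noisier and cross a fixed threshold more often, so null comparisons
must match frame counts.

## Adaptive-optics simulation

Scalar 2D Fourier optics at the focal plane: pupil amplitude is a circular
mask, phase is Σ c_k Z_k over Noll-indexed Zernikes normalized to unit RMS
over the pupil (piston excluded; container indexed from Noll 2). The basis
grid must resolve the highest radial order (≥4 px per fringe at the pupil
edge; ≥4n px enforced). One-photon focal intensity is |ℱ|² on a ≥2×
zero-padded grid, normalized to unit sum — fixed average excitation power
regardless of aberration. Two-photon excitation is its square; its **total**
falls as aberration spreads the focus, and the forward model keeps that
physical total when simulating images, which is exactly why mean image
intensity works as the feedback metric. A unit-sum normalization of the
two-photon PSF is the default for shape analyses only. Strehl is the
one-photon peak ratio against the flat pupil and follows the Maréchal
approximation e^(−σ²) to within 5 % up to σ = 0.5 rad.

The optimizer scans each mode over a symmetric range (default ±1.5 rad,
odd step count so 0 is tested), averages the metric curves over the cycle
budget, and fixes the argmax before the next mode. Two numerical
safeguards: near-flat curves (relative spread ≤ 10⁻⁶, e.g. tip/tilt, which
only translate the image) select zero correction, and exact ties prefer
the smallest correction. Recovery studies scan from Noll 4 — standard
sensorless practice, since an intensity metric cannot sense image
translation. For large mixed aberrations single-sweep sequential
correction converges to *balanced* rather than nulled coefficients
(spherical aberration shifts the optimal defocus); the `n_passes` option
distributes the cycle budget over repeated sweeps of the mode sequence,
which converges to the null while spending exactly
modes × steps × cycles transitions. At 1.2 rad RMS over ten modes under
photon noise (≈2×10⁵ photons per unit intensity, metric SNR ≫ 1 after
image averaging), five sweeps recover 86–93 % of the aberration; a single
sweep recovers only ~40 %. Desk-scale defaults are 10–15 modes on a 64 px
pupil with a 128² sample (~1 k evaluations, seconds); the full
200-mode × 21 × 5 = 21 000-transition budget runs in about two minutes
and is exercised by the acceptance script. No 3D/vectorial diffraction,
tissue scattering, or actuator-space modelling.

## Resolution characterization

Bead detection is a local-maximum filter above a prominence threshold
(default 0.3 × global peak); peaks are refined per axis by quadratic
interpolation before line profiles are taken, avoiding half-voxel bias at
the ~10:1 axial anisotropy. Each axis profile is fit with
A·exp(−(x−µ)²/2σ²) + offset by least squares (the offset term is a
declared choice); FWHM = 2√(2 ln 2)·σ; fits failing to converge or with
R² < 0.5 raise with diagnostics. Beads whose fitted centre lies within
3 × FWHM of a stack border are excluded from summaries. Recovery matches
the Gaussian-convolution closed form within 2 %.

Geometry: area = π(d/2)², volume = area × depth, SBP = area/resolution².
For an 8 mm field, 0.9 mm depth and 1 µm lateral resolution these round to
50.27 mm², 45.24 mm³ and 5.03×10⁷.

## Known limitations

- The generators' realism is structural, not photometric: no shot-noise
  scaling with depth, no bleaching, no motion in the calcium movies.
- Skeleton-derived lengths depend on end erosion (~one tube radius at free
  ends); comparisons should use the skeleton's own extent or tubes clipped
  at volume faces.
- Discrete skeletonization is not exactly rotation-equivariant; junction
  metrics agree across 90° rotations only to a few percent.
- The AO forward model is 2D and noise-free in its optics; metric noise
  enters only through the photon/read-noise model.
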