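# mesokit

Analysis computations for mesoscale two-photon microscopy of the mouse
cortex, exercised end-to-end on synthetic data with known ground truth.

Large field-of-view two-photon systems image an Ø8 mm field at ~1 µm
lateral resolution, deep enough (≈900 µm) to cover both superficial and
deep cortical layers. Turning such recordings into science requires four
distinct computations, all implemented here as a tested library:

1. **Vascular morphometry** (`mesokit.vascular`) — from a 3D angiogram
   stack: preprocessing, segmentation, skeletonization, and per-segment
   metrics. With `r_j = min(dist(v_j, background))` the radius at
   centerline point `v_j`,

   - diameter `D = 2 · median(r_j)`,
   - length `L = Σᵢ ‖p_{i+1} − p_i‖` along the centerline,
   - inter-vessel distance `IVD` = minimum Euclidean distance between
     segment midpoints,
   - density `ρ = V_vessel / V_ROI`.

2. **Calcium trace analysis** (`mesokit.calcium`) — ROI trace extraction,
   neuropil subtraction `f_corr = f − c·f_neuropil`, baseline
   `f₀ = 15th percentile` of the full recording, `ΔF/F = (f − f₀)/f₀`,
   transient-based SNR, Pearson correlation matrices and
   correlation-vs-distance profiles.

3. **Functional connectivity** (`mesokit.network`) — locomotion-state
   classification from treadmill/platform speed, thresholded correlation
   graphs (edges where `r > 0.3`, intra- vs inter-regional counts,
   stationary vs moving contrast) and per-node graph metrics (degree,
   clustering coefficient, strength at threshold `r > 0.1`).

4. **Sensorless adaptive optics** (`mesokit.ao`) — a Fourier-optics
   simulation of modal wavefront correction: Noll-indexed, RMS-normalized
   Zernike modes on a circular pupil, two-photon PSF `∝ |ℱ(A e^{iφ})|⁴`,
   and mode-by-mode optimization of mean image intensity (21 steps per
   cycle, 5 cycles per mode; 200 modes supported).

5. **Resolution characterization** (`mesokit.resolution`) — Gaussian FWHM
   fits (`FWHM = 2√(2 ln 2)·σ`) to bead z-stack profiles, the 25-point
   field sampling layout (centre + rings at 1.33/2.66/3.99 mm, 45°
   spacing), and analytic geometry (FOV area, imaged volume, spatial
   bandwidth product).

All inputs are produced by `mesokit.synthetic`: tubular phantoms with exact
centerline/radius ground truth, spiking calcium scenes whose region-shared
drive is amplified during locomotion, Gaussian bead stacks whose imaged
width obeys the closed form `FWHM_obs = √(FWHM_PSF² + FWHM_bead²)`, and
sparse "pollen-like" samples for the AO metric. Every generator is a pure
function of (spec, seed).

## Worked example

The numbered scripts under `analysis/` run the full pipelines on generated
data (run `01_simulate_data.py` first; outputs land under `results/`).
`analysis/04_adaptive_optics.py` injects a 1.2 rad RMS mixed aberration
over ten Zernike modes and corrects it sensorlessly under photon noise:

```
injected aberration: 1.200 rad RMS over 10 modes (Noll 4-13)
residual after correction: 0.121 rad RMS (89.9% reduction)
metric: 3.125e-04 -> 1.713e-03 (x5.48)
Strehl ratio: 0.244 -> 0.985
coefficient transitions: 1050 (10 modes x 21 steps x 5 cycles)
```

The mean image intensity (the feedback metric) rises 5.5-fold because a
tighter focus concentrates photon density and two-photon excitation grows
with its square; the Strehl ratio recovers from 0.24 to 0.99.

`analysis/03_calcium_connectivity.py` reproduces the locomotion-state
contrast on a 60-neuron, 10-minute synthetic recording:

```
state fractions: stationary 72.4%, moving 27.6%
connectivity at threshold 0.3:
 scope  stationary  moving  delta
 intra           2     248    246
 inter           0       1      1
 total           2     249    247
```

Moving-state graphs are far denser than stationary ones because the
region-shared drive is amplified threefold during movement — the same
qualitative signature seen in vivo.

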