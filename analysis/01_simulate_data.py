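"""Generate the synthetic datasets used by the downstream analyses.

Writes a vascular tube phantom (TIFF + SWC ground truth), a region-coupled
calcium recording with its locomotion trace (CSV), a bead z-stack at the
instrument's measured resolution scale (TIFF), and a pollen-like AO sample,
all under results/data/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from mesokit import io
from mesokit.synthetic import (
    CalciumSceneSpec,
    PhantomSpec,
    generate_ao_sample,
    generate_bead_stack,
    generate_calcium_traces,
    generate_vascular_phantom,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

# --- vascular phantom: Y junction, capillary-scale radii -------------------
center = (30.0, 50.0, 50.0)
phantom = PhantomSpec(
    shape_voxels=(60, 100, 100),
    spacing_um=(1.0, 1.0, 1.0),
    segments=[
        (center, (58.0, 50.0, 50.0), 4.0),
        (center, (5.0, 80.0, 50.0), 4.0),
        (center, (5.0, 20.0, 50.0), 4.0),
    ],
    noise_sd=0.05,
)
stack, truth = generate_vascular_phantom(phantom, seed=SEED)
io.write_tiff(OUT / "vascular_phantom.tif", stack)
io.write_swc(OUT / "vascular_truth.swc", truth.centerlines)
print(f"vascular phantom: {stack.shape} voxels, "
      f"{truth.centerlines.n_segments} true segments -> vascular_phantom.tif")

# --- calcium recording ------------------------------------------------------
scene = CalciumSceneSpec(
    n_neurons=60, n_regions=3, duration_s=600.0, frame_rate_hz=7.0,
    intra_region_coupling=0.8, inter_region_coupling=0.1, moving_gain=3.0,
    seed=SEED,
)
f, f_np, ca_truth, loco = generate_calcium_traces(scene)
pd.DataFrame(f).to_csv(OUT / "calcium_f.csv", index=False)
pd.DataFrame(f_np).to_csv(OUT / "calcium_neuropil.csv", index=False)
pd.DataFrame({
    "region": ca_truth.region_labels,
    "y_um": ca_truth.positions_um[:, 0],
    "x_um": ca_truth.positions_um[:, 1],
}).to_csv(OUT / "calcium_rois.csv", index=False)
pd.DataFrame({"speed_mm_s": loco.speed_mm_s}).to_csv(OUT / "locomotion.csv", index=False)
print(f"calcium scene: {f.shape[0]} neurons x {f.shape[1]} frames at "
      f"{scene.frame_rate_hz} Hz, moving fraction "
      f"{ca_truth.state_mask.mean():.2f} -> calcium_*.csv")

# --- bead stack -------------------------------------------------------------
positions = [(40.0, 6.0, 8.0), (40.0, 9.0, 14.0), (40.0, 12.0, 10.0),
             (40.0, 15.0, 17.0), (40.0, 18.0, 12.0)]
beads, bead_truth = generate_bead_stack(
    (10.88, 1.05, 1.05), (1e-6, 1e-6, 1e-6), positions,
    spacing_um=(0.27, 0.056, 0.056), noise_sd=0.002, seed=SEED,
)
io.write_tiff(OUT / "bead_stack.tif", beads)
io.write_json(OUT / "bead_truth.json", {
    "psf_fwhm_um": bead_truth.true_psf_fwhm_um,
    "observed_fwhm_um": bead_truth.observed_fwhm_um,
    "positions_um": positions,
})
print(f"bead stack: {beads.shape} voxels, 5 beads, PSF FWHM (z,y,x) = "
      f"(10.88, 1.05, 1.05) um -> bead_stack.tif")

# --- AO sample --------------------------------------------------------------
sample = generate_ao_sample(128, 8, seed=SEED)
np.savetxt(OUT / "ao_sample.csv", sample, delimiter=",")
print(f"AO sample: {sample.shape} px, 8 grains -> ao_sample.csv")
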