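# vtscope

Quantitative 3D image analysis and drug-effect ranking for **vascularized
tumor spheroids (VTSs)** — self-organizing co-cultures of tumor cells,
fibroblasts, endothelial cells and macrophage-like cells imaged by
light-sheet fluorescence microscopy.  The package is aimed at groups who
screen tumor-microenvironment-targeted drugs on such spheroids and need
the imaging readout turned into numbers that can be compared, ranked and
reproduced.

From a multichannel stack (anisotropic voxels, typically
0.5 × 0.5 × 1 µm) the pipeline produces, per spheroid:

* **Preprocessing** — 3D median denoising, an additively combined channel,
  and a smoothed delineation of the spheroid body (10 µm surface detail).
* **Compartment segmentation** — per-channel foreground masks (2 µm surface
  detail), connected objects, and point-like cells detected as ~10 µm orbs
  by a Laplacian-of-Gaussian detector.
* **Pseudovessel tracing** — skeletonization of the CD31 mask into
  connected networks of segments with length, mean diameter (from the
  anisotropic Euclidean distance transform) and **branch level**, the
  hierarchical distance of a segment from the longest (main) branch of its
  network.
* **Distance-field analysis** — per-voxel distance to the nearest vessel
  inside the spheroid, distance histograms, cell-to-structure distances,
  Col IV/vessel association, and the **supply index**
  `SI = (relative CD31⁺ volume in %) / (median vessel distance in µm)`.
* **Descriptors** — a versioned registry of named parameters; the full
  six-channel staining panel yields exactly **71** parameters, the
  three-cellular-channel configuration the **46**-parameter core.
* **Ranking** — the **vascular effect index**

  ```
  VEI = x1·(V_T/V_0)^y1 + x2·(SI_T/SI_0)^y2 + x3·(S/N_T / S/N_0)^y3
  ```

  a weighted power law over treated/control ratios of vessel volume,
  supply index and segments-per-network, calibrated against mean human
  observer scores by a two-stage fit (OLS for the weights, then bounded
  nonlinear least squares).  The shipped reference calibration is
  x = (0.6, −0.11, 0.44), y = (0.65, 1.5, 1.5).  Compartment effect
  indices map ratios onto the bounded scale b(r) = (r−1)/(r+1) ∈ (−1, +1).
* **Statistics** — standardized PCA of descriptor tables, inter-assay
  SDm (%), and Welch t tests.

A seeded **phantom generator** renders synthetic spheroids (body,
branching vessel trees, cell orbs, PSF blur, Poisson/Gaussian noise) with
full ground truth, so the entire pipeline is testable without microscope
data.

## Worked example

```python
import numpy as np
from vtscope import (PhantomSpec, CellParams, generate_phantom,
                     compute_descriptors, fit_vei_model,
                     generate_ranking_dataset)

# a 30 µm-radius phantom with 10 tumor and 10 fibroblast cells
spec = PhantomSpec(spheroid_radius=30.0, margin=5.0,
                   cell_params={"tumor": CellParams(count=10),
                                "fibroblast": CellParams(count=10)},
                   seed=3)
stack, truth = generate_phantom(spec)
row = compute_descriptors(stack, sample="demo")
print(row[["vts_volume_um3", "tumor_cell_count", "pv_total_length_um",
           "pv_supply_index"]].round(3).to_string(index=False))
#  vts_volume_um3  tumor_cell_count  pv_total_length_um  pv_supply_index
#        105567.5                10             119.025            0.274

# calibrate the VEI model on a synthetic observer-score table
table = generate_ranking_dataset(200, noise_sd=0.02, seed=1)
model = fit_vei_model(table)
print(model.weights_.round(3), model.exponents_.round(3))
# [ 0.593 -0.104  0.438] [0.657 1.54  1.503]
```

The descriptor row says the phantom body measures ~1.06 × 10⁵ µm³, all
ten tumor orbs were found, ~119 µm of pseudovessel centerline was traced,
and the vessel supply index is 0.27 (%/µm).  The fitted weights and
exponents recover the reference calibration from noisy synthetic scores.

A thin CLI wraps the library: `vtscope simulate stack`, `vtscope analyze`,
`vtscope rank fit`, `vtscope stats pca` (see `vtscope --help`).

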