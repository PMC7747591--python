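# cordmt

Tract-wise magnetization-transfer (MT) analysis of axial cervical spinal cord
MRI, built around the **MTR homogeneity index (MTRh)** — a
participant-normalized statistic designed to detect subtle, focal white-matter
demyelination that a plain tract-mean comparison would miss — together with a
synthetic cord-phantom generator that provides ground truth for every stage.

It is intended for researchers studying spinal cord microstructure after
trauma (e.g. whiplash after a motor vehicle collision), where a candidate cord
insult is radiologically occult: tract mean MTR values barely move, but the
*dispersion* of MTR across tracts does.

## The measurements

MT imaging acquires two co-registered images per slice: `I_o` (no saturation
pulse) and `I_MT` (off-resonance pulse that saturates macromolecule-bound
protons, e.g. myelin). The magnetization transfer ratio is the percent signal
drop:

```
MTR = (I_o − I_MT) / I_o × 100%
```

Per slice, MTR is averaged over eight white-matter tracts (left/right lateral
corticospinal tracts, cuneate and gracile fasciculi, and combined
spinothalamic + spinoreticular tracts). The homogeneity index over the tract
values x_A (N_A = 8) is

```
MTRh = sqrt(N_A / (N_A − 1)) · sqrt( Σ(x_A − x̄)² / Σ x_A² )
```

MTRh is 0 when all tracts agree, at most 1 for nonnegative values, and
invariant to rescaling all tracts by a common factor — the normalization by
`Σx²` removes participant- and coil-load-dependent signal scale. Algebraically
it is the fractional-anisotropy formula applied to the tract-value vector.

## Pipeline

| module            | role |
|-------------------|------|
| `cordmt.phantom`  | synthetic cord slices: elliptical cord + butterfly grey matter, 8 tract sectors, CSF ring, Rician noise, inter-scan misalignment, focal lesions, whole cohorts with known ground truth |
| `cordmt.register` | intensity-based cord segmentation; rigid in-plane registration of `I_o` onto `I_MT` (center-of-mass init, then NCC maximization in a 35-voxel circular mask) |
| `cordmt.mtr`      | MTR maps; tract extraction by probability-weighted means (`mask_mean`) or a maximum-a-posteriori partial-volume fit (`map`) |
| `cordmt.mtrh`     | the MTRh index per slice |
| `cordmt.stats`    | three-stage group analysis: one-way ANOVA on outcome → outcome×sex ANOVA (Type III) → linear mixed model with LS-means, multiple imputation, NDI correlations |
| `cordmt.cli`      | `cordmt simulate / process / analyze / report` |

Outcome groups follow the Neck Disability Index at one year: recovered
(NDI < 10%), mild (10–28%), severe (> 28%).

## Worked example

```python
import numpy as np
from cordmt import (
    TissueParams, MisalignmentSpec, make_tract_atlas, simulate_slice_pair,
    segment_cord, register_rigid, resample, compute_mtr_map,
    extract_tract_values, compute_mtrh,
)

atlas = make_tract_atlas()
tissue = TissueParams(noise_sigma=5.0)            # SNR 20 in white matter
pair = simulate_slice_pair(
    atlas, tissue,
    misalign=MisalignmentSpec(2.0, -1.0, 3.0),    # inter-scan motion
    seed=1,
)

area = np.pi * 6.5 * 4.25                         # expected cord area, mm^2
mask_o, _ = segment_cord(pair.i_o, 0.5, area)
mask_mt, _ = segment_cord(pair.i_mt, 0.5, area)
t = register_rigid(pair.i_o, pair.i_mt, mask_o, mask_mt)
print(f"recovered shift ({t.tx_vox:+.2f}, {t.ty_vox:+.2f}) vox, "
      f"rotation {t.theta_deg:+.2f} deg, NCC {t.ncc:.3f}")

mtr_map = compute_mtr_map(resample(pair.i_o, t), pair.i_mt, atlas.cord_mask)
table = extract_tract_values(mtr_map, atlas, method="map")
print(table[["tract", "mtr_percent"]].round(2).to_string(index=False))
print(f"MTRh = {compute_mtrh(table['mtr_percent']):.4f}")
```

prints

```
recovered shift (-2.05, +0.90) vox, rotation -2.91 deg, NCC 0.962
 tract  mtr_percent
 CST_L        40.00
 CST_R        40.03
  CF_L        37.95
  CF_R        36.56
  GF_L        38.96
  GF_R        39.26
SPTH_L        39.19
SPTH_R        39.93
MTRh = 0.0308
```

The recovered transform is close to the inverse of the injected misalignment
(the exact inverse of a (+2, −1, +3°) motion about the cord centroid is
(−2.05, +0.89, −3°); the residual rotation error here is under a tenth of a
degree at SNR 20). The tract values scatter around their generating baselines
(39.5–40.5%), and the small MTRh says this slice is homogeneous — no focal
insult. The same slice with `LesionSpec(("SPTH_L",), 5.0, 1.0)` — one tract
dropped by 5 percentage points — raises MTRh to 0.0528.

A full cohort run from the shell:

```bash
cordmt simulate --outdir run --seed 1
cordmt process  --outdir run --seed 1 --method map
cordmt analyze  --outdir run --seed 1
cordmt report   --outdir run
```

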