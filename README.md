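# periomri

Quantification of periodontal bone-marrow edema from longitudinal dental
MRI, with a fully ground-truthed synthetic test bed.

Periodontitis drives inflammatory infiltration of the tooth-supporting
alveolar bone that appears as hyperintense marrow signal on fat-suppressed
T2 (STIR) sequences well before X-ray-visible bone loss. Monitoring that
edema across a treatment interval requires: rigidly co-registering the
follow-up scan into the baseline frame, deciding voxel-by-voxel what counts
as edema, differencing the two timepoints, and relating the imaging
readouts to standard clinical probing findings. `periomri` implements this
chain for researchers developing MRI biomarkers of periodontal disease, and
ships a phantom generator plus a clinical site-table simulator so every
stage can be validated against known ground truth without patient data.

## Method

* **Edema rule.** Let μ, σ be the mean and SD of signal in an operator-drawn
  edema-free reference marrow volume. A voxel inside a quadrant ROI and the
  bony compartment is edema iff its STIR signal exceeds μ + kσ (strict;
  k = 2 by default). On noise-only marrow this rule classifies a fraction
  Φ̄(k) = 0.02275 of voxels by construction, so volumetry additionally uses a
  minimum-cluster filter, a per-lesion half-maximum rim bound and interior
  hole filling (see `docs/methods.md`).
* **Change maps.** With the follow-up scan registered into the baseline
  frame (6-DOF rigid transform estimated by deterministic multi-resolution
  descent on mean squared intensity difference), the pre-minus-post and
  post-minus-pre subtractions reduce to set differences of the two binary
  edema maps: reduction = E₀ ∖ E₁, new = E₁ ∖ E₀, stable = E₀ ∩ E₁, each in
  mm³ as voxel count × voxel volume (0.65³ mm³ at the default isotropic
  0.65 mm spacing).
* **Edema depth (ED).** At each of six probing sites per molar
  (buccal/lingual × anterior/mid/posterior), the ray from the alveolar
  crest along the apical direction is sampled at quarter-voxel steps; ED is
  the length of the longest contiguous run of edema samples, in mm.
* **Statistics.** Sites are stratified by baseline findings (PPD ≤ 3 mm
  without/with BOP, PPD 4–5 mm, PPD ≥ 6 mm). Median [IQR] summaries, paired
  Wilcoxon signed-rank (exact enumeration for small n, tie-corrected normal
  otherwise), Mann-Whitney U, and Pearson chi-square (Yates correction on
  2×2) reproduce the standard before/after summary tables.

## Worked example

```python
import numpy as np
from periomri import (
    LesionSpec, PhantomConfig, RigidTransform,
    generate_phantom, estimate_rigid, quantify_bundle,
)

true_move = RigidTransform.from_euler(np.radians([2, -1, 0.5]),
                                      [1.5, -1.0, 1.0], [20.475] * 3)
cfg = PhantomConfig(
    lesions_t0=[LesionSpec((20, 20, 15), (6, 5.5, 6.5), 5.0)],   # baseline lesion
    lesions_t1=[LesionSpec((20, 20, 15), (4.5, 4.0, 5.0), 5.0)], # shrunken at follow-up
    true_transform=true_move, seed=11,
)
bundle = generate_phantom(cfg)
transform = estimate_rigid(bundle.stir_t0, bundle.stir_t1).transform
report = quantify_bundle(bundle, transform)
shell = bundle.truth.volume_t0_mm3 - bundle.truth.volume_t1_mm3
reduction = sum(q["reduction_mm3"] for q in report["quadrants"].values())
new = sum(q["new_mm3"] for q in report["quadrants"].values())
print(f"true shell {shell:.0f} mm3, measured reduction {reduction:.0f} mm3, "
      f"spurious new {new:.0f} mm3")
```

prints

```
true shell 518 mm3, measured reduction 530 mm3, spurious new 4 mm3
```

i.e. the pipeline recovers the 518 mm³ of truly resolved edema to within
2.5% while attributing under 1% of it to spurious "new" edema, despite the
follow-up scan being misaligned by 2°/1.8 mm and carrying SNR-10 noise.

A command-line interface mirrors the library:
`periomri simulate phantom|sites`, `periomri register`, `periomri
quantify`, `periomri stats`, and `periomri run` for the full
simulate → register → quantify → stats pipeline with a reproducibility
manifest.

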