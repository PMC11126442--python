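# Methods

This note documents the models, conventions, parameter choices and known
limitations of `periomri`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and grid conventions

All volumes are axis-aligned scalar grids (`ImageVolume`) with RAS-like
axes, affine = diag(spacing), origin at the volume corner, 0-based voxel
indices, and the center of voxel *i* at `i * spacing + origin` (mm). The
default spacing is isotropic 0.65 mm, so one voxel is 0.65³ ≈ 0.2746 mm³.
NIfTI-1 is the on-disk format; only diagonal affines are accepted on load
(negative axis scalings are folded into the data).

A `RigidTransform` acts on world coordinates as `p' = R(p − c) + c + t`
(rotation matrix `R` orthonormal to 1e-9, center `c`, translation `t`, all
mm; Euler angles xyz extrinsic in radians for serialization).
`resample(vol, T)` produces `out(x) = vol(T⁻¹(x))` on the same grid —
trilinear for intensities, nearest for masks/labels.

## Synthetic imaging phantom

The phantom emulates the *measurement situation*, not jaw anatomy or pulse
sequence physics: a rectangular bone slab (cortical shell 2 voxels thick,
marrow interior) inside soft tissue, on a 64³ grid by default. Signal
levels are relative to the marrow mean (default 100): STIR soft tissue
0.60, cortical bone 0.15, marrow 1.0; the T1 companion (used only to
derive the bone mask) has cortex 0.10 and soft tissue 0.80, i.e. inverted
bone/marrow contrast.

* **Lesions** are ellipsoids specified by center, semi-axes (mm) and core
  contrast in reference-SD units. Intensity is blended with a raised-cosine
  edge one voxel wide across the surface, so partial-volume behaviour
  exists; ground-truth masks digitize voxel centers with normalized radius
  ≤ 1, and truth volumes are exactly mask count × voxel volume.
* **Noise** is Gaussian by default, SD equal to the marrow SD (default 10,
  i.e. SNR 10); a Rician option (magnitude of two Gaussian channels) exists
  because magnitude-MRI noise is Rician, but the analytic 2 SD
  false-positive rate is exact only under the Gaussian model, which the
  validation studies therefore use. The scanner's true intensity units and
  SNR are unpublished; these are free parameters.
* **Misalignment**: the follow-up anatomy is built noiseless in the
  baseline frame, pushed through the configured true transform, and noise
  is added afterwards — the order in which repositioning and acquisition
  noise arise physically. Registration should recover the inverse of the
  configured transform.
* **Derived masks**: quadrant ROIs split the marrow interior at the x/y
  midlines; the reference-marrow mask is the interior eroded by 2 voxels
  minus all lesion masks dilated by 3, guaranteeing an edema-free
  reference. Six probing sites per simulated tooth sit on the crest with
  the apical direction pointing into the bone; true site depths are
  analytic ray-ellipsoid chord lengths (longest merged interval across
  lesions).

Identical configs (including seed) produce bit-identical bundles.

## Edema classification and volumetry

The classification rule is deliberately minimal: voxel ∈ ROI ∩ bone and
signal strictly above μ + kσ of the reference marrow, k = 2 by default,
with each scan standardized against its own reference statistics (removes
inter-scan gain drift; the threshold is a per-scan z > k). No cluster
filter is applied by default. Three optional, explicitly-parameterized
refinements serve volumetry and depth measurement:

1. **Minimum-cluster filter** (26-connectivity, default 10 voxels in the
   pipeline): the k = 2 rule classifies Φ̄(2) = 2.275% of noise-only marrow
   voxels by construction, almost always as isolated voxels; without the
   filter every volume estimate carries that floor (~0.6 mm³ per ROI cm³·%).
   Ten-voxel noise clusters are practically impossible under i.i.d. noise,
   while any detectable lesion greatly exceeds the size.
2. **Half-maximum rim bound** (`refine_partial_volume`): with a smooth
   lesion edge the μ + kσ iso-surface lies *outside* the true boundary
   whenever core contrast exceeds 2k SD, biasing counts by up to ~+12% for
   100 mm³ lesions at +6 SD. Each connected component is therefore bounded
   at half its own core contrast (FWHM criterion, core estimated as the
   median over the eroded interior), never below the k-SD rule, so the
   refined mask is a subset of the classified mask.
3. **Interior hole filling** (`fill_interior_holes`): noise pulls interior
   voxels below threshold with probability Φ(−margin), splitting the
   contiguous runs that depth measurement relies on; binary hole filling
   restores fully enclosed dropouts without moving any boundary.

**Change maps.** Classification is applied per timepoint and change maps
are mask differences (reduction = E₀ ∖ E₁, new = E₁ ∖ E₀, stable = E₀ ∩ E₁).
The alternative — thresholding subtraction intensities — was rejected
because the k-SD criterion is defined relative to marrow signal, not signal
change; a `threshold_subtraction` variant is not offered for that reason.
The conservation identities reduction + stable = |E₀| and new + stable =
|E₁| hold exactly for all inputs.

**Native-frame follow-up classification.** The follow-up scan is
thresholded in its native frame (masks carried over by the inverse
transform with nearest lookup) and only the binary map is resampled into
the baseline frame. Thresholding a trilinearly resampled volume instead
operates on spatially correlated noise whose local variance depends on the
fractional resampling offsets; correlated false positives then form
clusters that defeat the minimum-cluster filter (measured: spurious "new"
edema of ~12% vs ~1% of a known shell volume).

**Edema depth.** Quarter-voxel ray sampling with nearest-voxel lookup;
ED = longest contiguous run (a length of edematous marrow, not the
crest-to-deepest-voxel span), 0 when no sample is edema, optional half-up
rounding to integer mm for site records (summaries use rounded values,
matching integer-mm probe readings). Digitization bounds the error at
roughly one voxel. Per-tooth ED is the maximum over the (up to six)
site values.

## Rigid registration

6-DOF estimation by Powell descent over (3 Euler angles in degrees, 3
translations in mm), rotation centered at the fixed volume's center, on a
3-level Gaussian pyramid (downsampling factors 4/2/1), minimizing mean
squared intensity difference (default; a negative-correlation metric is
available for cross-contrast pairs). All schedules are fixed and nothing is
sampled stochastically, so results are bit-reproducible given identical
inputs and options. Out-of-domain samples take the moving volume's border
median. Non-convergence is carried as a warning status in the result, not
an exception. On noiseless phantoms misaligned by up to 5°/5 mm the target
registration error at the bone corners is well below one voxel (recomputed
by `scripts/acceptance.py`). No claim of equivalence to any specific
external registration package is made, since published parameter files do
not exist for the study setting this emulates.

## Clinical site-table simulator

`generate_site_table` draws paired baseline/follow-up records per probing
site: a baseline stratum from `category_probs_t0` over (PPD ≤ 3 no BOP,
PPD ≤ 3 BOP, PPD 4–5, PPD ≥ 6) = (0.342, 0.178, 0.330, 0.150), integer PPD
within the stratum, BOP in deeper strata with probabilities (0.55, 0.85)
falling to (0.35, 0.50), baseline edema presence per stratum with
probabilities (0.18, 0.30, 0.30, 0.92) — calibrated so ~35% of sites carry
edema overall — and integer ED (mm) from per-stratum distributions whose
median [IQR] equal 2 [1,3] / 1 [1,3] / 1 [1,2] / 2 [2,5] at baseline and
2 [1,3] / 1 [0,3] / 1 [0,2] / 1 [0,3] at follow-up (mass at 0 =
resolved edema; a 2% new-edema probability applies to initially
edema-free sites). Follow-up PPD/BOP strata are drawn independently from
`category_probs_t1` = (0.42, 0.15, 0.31, 0.12): the published before/after
category comparison is unpaired, and this choice reproduces exactly that
analysis. Consequently the *within-stratum paired* PPD tests on simulated
tables are not calibrated — a known, accepted limitation. An optional
`n_sites` truncates to an exact cohort size (e.g. 922), which the
patients × teeth × 6 grid cannot hit exactly.

## Statistics

* Percentiles: linear interpolation, recorded in table metadata.
* Percentages: half-up rounding to integer, denominators always explicit.
* Wilcoxon signed-rank: zero differences dropped (classical reduction),
  mid-ranks for tied |differences|, two-sided p = P(|T − E[T]| ≥ |t − E[T]|).
  Exact null by convolution over sign assignments for n ≤ 12; otherwise
  tie-corrected normal approximation without continuity correction
  (software defaults differ on both points, hence the explicit record).
* Mann-Whitney U: exact enumeration when both groups ≤ 8 (or pooled ≤ 12),
  else tie-corrected normal approximation; U reported for the first group.
* Chi-square: Pearson, Yates continuity correction iff 2×2 (auto mode).
  The before/after category-band comparison uses the unpaired 2×3 test
  without correction — replicating the published analysis despite the
  paired sites; a marginal-homogeneity test would be the paired
  alternative and is deliberately not substituted.
* Two-tailed throughout, α = 0.05, no multiplicity adjustment (matching
  the emulated analysis).
* Degenerate cases: all-zero differences → p = 1 with a degenerate flag;
  a contingency row/column of zeros raises, except the all-sites-affected
  row of the edema table which reports p = NaN when no site is affected.

## Validation studies and problem sizes

The studies in `periomri.validation` (used by both the test suite and the
reproduction script) run at sizes chosen to keep a full run in minutes on
one core while leaving the statistical bounds meaningful: null-rate check
on an 80³ phantom (ROI > 1.4×10⁵ voxels, 3-binomial-SE band), 20
single-lesion phantoms (volumes uniform 100–1000 mm³, mild anisotropy,
contrast uniform +4..+6 SD, SNR 10), one shrinking-lesion pair with a
2°/1.8 mm misalignment, eight depth phantoms per noise condition (extents
1–8 mm), two registration cases (3° and 5°/5 mm), 200 simulator replicates
for Wilcoxon power at ~320 affected sites, and one 922-site table for
frequency recovery.

## What passing tests do and do not show

The phantoms have piecewise-constant backgrounds, perfectly rigid motion,
spatially white noise and exactly ellipsoidal lesions. Real dental MRI adds
susceptibility and motion artifacts from restorations (excluded teeth in
practice), anatomically irregular marrow spaces, partial-volume mixing with
trabecular structure, bias fields, and manual-segmentation variability in
the ROI and reference masks — none of which are modeled. Recovery of
ground truth here validates the *computational* chain (registration,
thresholding statistics, volumetry arithmetic, depth geometry), not
clinical accuracy. Patient-level published medians and volumetric means
are not reproducible from synthetic data and are deliberately out of
scope; the simulator instead verifies that the table builders and tests
recover the statistical structure they were calibrated to.
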