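"""Ground-truthed synthetic inputs for the edema-quantification pipeline.

Two kinds of synthetic data are produced:

* **Imaging phantoms** (:func:`generate_phantom`): paired STIR-like and
  T1-black-bone-like volumes at two timepoints on a 0.65 mm isotropic grid,
  containing an alveolar-ridge-like bone slab with marrow, ellipsoidal
  hyperintense edema lesions of known geometry, a known rigid misalignment of
  the follow-up scan, and Gaussian or Rician scanner noise. Every derived
  quantity (lesion masks, volumes in mm^3, per-site apical-coronal extents)
  is returned as ground truth.

* **Clinical site tables** (:func:`generate_site_table`): per-site probing
  pocket depth (PPD), bleeding on probing (BOP) and edema depth (ED) records
  at baseline and follow-up, drawn from configurable per-category
  distributions whose defaults are calibrated to the published frequency
  structure of a periodontitis treatment cohort (PPD bands 52/33/15% at
  baseline shifting to 57/31/12%, ~35% of sites with edema falling to ~24%,
  stratum ED medians 2 [1, 3] mm falling to 1 [0, 3] mm).

The phantoms emulate geometry, contrast, misalignment and noise — not pulse
sequence physics or real jaw anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageVolume
from .registration import RigidTransform, resample

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "PhantomTruth",
    "PhantomBundle",
    "ClinicalSimConfig",
    "generate_phantom",
    "generate_site_table",
    "save_bundle",
]

# signal levels relative to marrow_mean, piecewise-constant base anatomy
_STIR_SOFT = 0.60
_STIR_CORTEX = 0.15
_T1_SOFT = 0.80
_T1_CORTEX = 0.10


@dataclass
class LesionSpec:
    """An ellipsoidal edema lesion.

    ``contrast_sd`` is the intensity added at the lesion core, in units of
    the reference marrow SD; detectable lesions need contrast above the
    classification threshold (k = 2 by default).
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    contrast_sd: float

    def __post_init__(self) -> None:
        if not all(a > 0 for a in self.semi_axes_mm):
            raise ValueError(f"lesion semi-axes must be positive, got {self.semi_axes_mm}")


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.65
    marrow_mean: float = 100.0
    marrow_sd: float = 10.0
    lesions_t0: list[LesionSpec] = field(default_factory=list)
    lesions_t1: list[LesionSpec] = field(default_factory=list)
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_model: str = "gaussian"
    noise_sd: float | None = None  # None -> marrow_sd; 0 disables noise
    n_teeth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.marrow_sd < 0:
            raise ValueError("marrow_sd must be non-negative")

    @property
    def effective_noise_sd(self) -> float:
        return self.marrow_sd if self.noise_sd is None else self.noise_sd

    def to_json(self, path: str) -> None:
        d = asdict(self)
        d["true_transform"] = self.true_transform.to_dict()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PhantomConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["true_transform"] = RigidTransform.from_dict(d["true_transform"])
        d["lesions_t0"] = [LesionSpec(tuple(l["center_mm"]), tuple(l["semi_axes_mm"]), l["contrast_sd"]) for l in d["lesions_t0"]]
        d["lesions_t1"] = [LesionSpec(tuple(l["center_mm"]), tuple(l["semi_axes_mm"]), l["contrast_sd"]) for l in d["lesions_t1"]]
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class ToothSite:
    """One of six probing positions on a tooth (FDI numbering).

    ``crest_point`` is the mm coordinate at the alveolar crest where the
    measurement ray starts; ``apical_dir`` is the unit apical-coronal axis
    pointing apically (into the bone).
    """

    tooth_id: int
    position: str  # {buccal,lingual}-{anterior,mid,posterior}
    crest_point: np.ndarray
    apical_dir: np.ndarray

    POSITIONS = (
        "buccal-anterior", "buccal-mid", "buccal-posterior",
        "lingual-anterior", "lingual-mid", "lingual-posterior",
    )

    def __post_init__(self) -> None:
        self.crest_point = np.asarray(self.crest_point, dtype=float).reshape(3)
        self.apical_dir = np.asarray(self.apical_dir, dtype=float).reshape(3)
        if self.position not in self.POSITIONS:
            raise ValueError(f"unknown site position {self.position!r}")
        n = np.linalg.norm(self.apical_dir)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("apical_dir must be a non-zero vector")
            self.apical_dir = self.apical_dir / n


@dataclass
class PhantomTruth:
    lesion_mask_t0: ImageVolume
    lesion_mask_t1: ImageVolume
    volume_t0_mm3: float
    volume_t1_mm3: float
    site_depths_t0_mm: np.ndarray
    site_depths_t1_mm: np.ndarray
    true_transform: RigidTransform


@dataclass
class PhantomBundle:
    stir_t0: ImageVolume
    stir_t1: ImageVolume
    t1bone_t0: ImageVolume
    t1bone_t1: ImageVolume
    roi_masks: dict[str, ImageVolume]
    marrow_ref_mask: ImageVolume
    bone_mask: ImageVolume
    sites: list[ToothSite]
    truth: PhantomTruth
    config: PhantomConfig


# ---------------------------------------------------------------------------
# imaging phantom


def _ellipsoid_fields(vol: ImageVolume, lesion: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Hard digitization mask (voxel centers inside) and soft blend weight.

    The blend weight falls from 1 to 0 over a raised-cosine band one voxel
    wide centered on the ellipsoid surface, so lesions exhibit
    partial-volume-like edges rather than binary steps.
    """
    xs, ys, zs = vol.voxel_centers()
    c = np.asarray(lesion.center_mm, dtype=float)
    a = np.asarray(lesion.semi_axes_mm, dtype=float)
    r = np.sqrt(
        ((xs - c[0]) / a[0]) ** 2
        + ((ys - c[1]) / a[1]) ** 2
        + ((zs - c[2]) / a[2]) ** 2
    )
    hard = r <= 1.0
    # half-width of the edge band in normalized-radius units: half a voxel
    # along the tightest axis
    h = 0.5 * float(vol.spacing.min()) / float(a.min())
    t = (r - 1.0) / h  # -1 .. 1 across the band
    w = np.where(t <= -1.0, 1.0, np.where(t >= 1.0, 0.0, 0.5 * (1.0 - np.sin(0.5 * np.pi * np.clip(t, -1, 1)))))
    return hard, w


def _check_lesion_inside(cfg: PhantomConfig, lesion: LesionSpec, name: str) -> None:
    extent = (np.array(cfg.grid_shape) - 1) * cfg.voxel_size_mm
    c = np.asarray(lesion.center_mm)
    a = np.asarray(lesion.semi_axes_mm)
    if np.any(c - a < 0) or np.any(c + a > extent):
        raise ValueError(
            f"lesion {name} (center {lesion.center_mm} mm, semi-axes "
            f"{lesion.semi_axes_mm} mm) extends outside the grid (0..{extent} mm)"
        )


def _bone_geometry(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bone slab, cortical shell and marrow interior as index masks."""
    nx, ny, nz = shape
    slab = np.zeros(shape, dtype=bool)
    x0, x1 = int(0.12 * nx), int(0.88 * nx)
    y0, y1 = int(0.12 * ny), int(0.88 * ny)
    z0, z1 = int(0.10 * nz), int(0.70 * nz)
    slab[x0:x1, y0:y1, z0:z1] = True
    interior = ndimage.binary_erosion(slab, iterations=2)
    cortex = slab & ~interior
    return slab, cortex, interior


def _ray_ellipsoid_chord(p0: np.ndarray, d: np.ndarray, lesion: LesionSpec) -> tuple[float, float] | None:
    """Parameter interval [t0, t1] (t >= 0) where the ray lies inside the lesion."""
    c = np.asarray(lesion.center_mm, dtype=float)
    a = np.asarray(lesion.semi_axes_mm, dtype=float)
    p = (p0 - c) / a
    q = d / a
    A = float(q @ q)
    B = 2.0 * float(p @ q)
    C = float(p @ p) - 1.0
    disc = B * B - 4 * A * C
    if disc <= 0 or A == 0:
        return None
    sq = np.sqrt(disc)
    lo, hi = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
    lo = max(lo, 0.0)
    if hi <= lo:
        return None
    return lo, hi


def _longest_merged_interval(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    best = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            best = max(best, cur_hi - cur_lo)
            cur_lo, cur_hi = lo, hi
    return max(best, cur_hi - cur_lo)


def true_site_depth(site: ToothSite, lesions: list[LesionSpec]) -> float:
    """Analytic apical-coronal extent (mm): longest contiguous stretch of the
    site's measurement ray inside any lesion."""
    chords = []
    for les in lesions:
        iv = _ray_ellipsoid_chord(site.crest_point, site.apical_dir, les)
        if iv is not None:
            chords.append(iv)
    return _longest_merged_interval(chords)


def _default_sites(vol: ImageVolume, interior: np.ndarray, n_teeth: int) -> list[ToothSite]:
    idx = np.argwhere(interior)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    z_crest = vol.index_to_world([0, 0, hi[2]])[2]
    yc = vol.index_to_world([0, (lo[1] + hi[1]) / 2.0, 0])[1]
    dy = 0.25 * (hi[1] - lo[1]) * vol.spacing[1]
    xs = np.linspace(lo[0] + 3, hi[0] - 3, n_teeth)
    dx = 1.5 * vol.spacing[0]
    sites: list[ToothSite] = []
    for i, xi in enumerate(xs):
        xw = vol.index_to_world([xi, 0, 0])[0]
        tooth_id = 36 + i  # mandibular left molar region, FDI
        for side, ys in (("buccal", yc + dy), ("lingual", yc - dy)):
            for pos, xo in (("anterior", -dx), ("mid", 0.0), ("posterior", dx)):
                sites.append(
                    ToothSite(
                        tooth_id=tooth_id,
                        position=f"{side}-{pos}",
                        crest_point=np.array([xw + xo, ys, z_crest]),
                        apical_dir=np.array([0.0, 0.0, -1.0]),
                    )
                )
    return sites


def _add_noise(data: np.ndarray, sd: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return data
    if model == "gaussian":
        return data + rng.normal(0.0, sd, size=data.shape)
    # Rician: magnitude of a complex signal with independent Gaussian channels
    n1 = rng.normal(0.0, sd, size=data.shape)
    n2 = rng.normal(0.0, sd, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2**2)


def generate_phantom(config: PhantomConfig) -> PhantomBundle:
    """Generate a fully ground-truthed paired-timepoint phantom.

    The follow-up (t1) volumes are built in the baseline frame and then
    pushed through ``config.true_transform`` before noise is added, emulating
    patient repositioning between scans; registration should recover
    ``config.true_transform.inverse()``. Identical configs (including seed)
    produce bit-identical bundles.
    """
    for i, les in enumerate(config.lesions_t0):
        _check_lesion_inside(config, les, f"t0[{i}]")
    for i, les in enumerate(config.lesions_t1):
        _check_lesion_inside(config, les, f"t1[{i}]")

    rng = np.random.default_rng(config.seed)
    spacing = np.array([config.voxel_size_mm] * 3)
    grid = ImageVolume(np.zeros(config.grid_shape, dtype=float), spacing)

    slab, cortex, interior = _bone_geometry(config.grid_shape)
    mm = config.marrow_mean

    def base(soft: float, cort: float) -> np.ndarray:
        img = np.full(config.grid_shape, soft * mm, dtype=float)
        img[cortex] = cort * mm
        img[interior] = mm
        return img

    stir_base = base(_STIR_SOFT, _STIR_CORTEX)
    t1_base = base(_T1_SOFT, _T1_CORTEX)

    def with_lesions(lesions: list[LesionSpec]) -> tuple[np.ndarray, np.ndarray]:
        img = stir_base.copy()
        hard_any = np.zeros(config.grid_shape, dtype=bool)
        for les in lesions:
            hard, w = _ellipsoid_fields(grid, les)
            img = img + w * les.contrast_sd * config.marrow_sd
            hard_any |= hard
        return img, hard_any

    stir0_clean, hard0 = with_lesions(config.lesions_t0)
    stir1_clean, hard1 = with_lesions(config.lesions_t1)

    noise_sd = config.effective_noise_sd
    tr = config.true_transform
    is_identity = (
        np.allclose(tr.rotation, np.eye(3)) and np.allclose(tr.translation, 0)
    )

    def scanned(clean: np.ndarray, move: bool, soft_fill: float) -> ImageVolume:
        vol = grid.like(clean)
        if move and not is_identity:
            vol = resample(vol, tr, "trilinear", fill_value=soft_fill)
        return grid.like(_add_noise(vol.data, noise_sd, config.noise_model, rng))

    stir_t0 = scanned(stir0_clean, False, _STIR_SOFT * mm)
    stir_t1 = scanned(stir1_clean, True, _STIR_SOFT * mm)
    t1bone_t0 = scanned(t1_base, False, _T1_SOFT * mm)
    t1bone_t1 = scanned(t1_base, True, _T1_SOFT * mm)

    bone_mask = grid.like(interior.astype(np.uint8))

    # quadrant ROIs: split the marrow interior by the x/y midlines
    idx = np.argwhere(interior)
    cx = (idx[:, 0].min() + idx[:, 0].max() + 1) // 2
    cy = (idx[:, 1].min() + idx[:, 1].max() + 1) // 2
    xs, ys = np.meshgrid(
        np.arange(config.grid_shape[0]), np.arange(config.grid_shape[1]), indexing="ij"
    )
    roi_masks: dict[str, ImageVolume] = {}
    for label, (xc, yc_) in {
        "Q1": (xs[:, :, None] < cx, ys[:, :, None] < cy),
        "Q2": (xs[:, :, None] >= cx, ys[:, :, None] < cy),
        "Q3": (xs[:, :, None] < cx, ys[:, :, None] >= cy),
        "Q4": (xs[:, :, None] >= cx, ys[:, :, None] >= cy),
    }.items():
        roi_masks[label] = grid.like((interior & xc & yc_).astype(np.uint8))

    # reference marrow: deep interior away from every lesion at either timepoint
    ref = ndimage.binary_erosion(interior, iterations=2)
    lesion_any = hard0 | hard1
    if lesion_any.any():
        ref &= ~ndimage.binary_dilation(lesion_any, iterations=3)
    marrow_ref_mask = grid.like(ref.astype(np.uint8))

    sites = _default_sites(grid, interior, config.n_teeth)
    vox_mm3 = grid.voxel_volume_mm3
    truth = PhantomTruth(
        lesion_mask_t0=grid.like(hard0.astype(np.uint8)),
        lesion_mask_t1=grid.like(hard1.astype(np.uint8)),
        volume_t0_mm3=float(hard0.sum()) * vox_mm3,
        volume_t1_mm3=float(hard1.sum()) * vox_mm3,
        site_depths_t0_mm=np.array([true_site_depth(s, config.lesions_t0) for s in sites]),
        site_depths_t1_mm=np.array([true_site_depth(s, config.lesions_t1) for s in sites]),
        true_transform=tr,
    )
    return PhantomBundle(
        stir_t0=stir_t0,
        stir_t1=stir_t1,
        t1bone_t0=t1bone_t0,
        t1bone_t1=t1bone_t1,
        roi_masks=roi_masks,
        marrow_ref_mask=marrow_ref_mask,
        bone_mask=bone_mask,
        sites=sites,
        truth=truth,
        config=config,
    )


def save_bundle(bundle: PhantomBundle, out_dir: str) -> dict[str, str]:
    """Write a bundle to ``out_dir`` (NIfTI volumes/masks, CSV tables, JSON)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def wv(name: str, vol: ImageVolume) -> None:
        p = os.path.join(out_dir, f"{name}.nii")
        vol.save_nifti(p)
        paths[name] = p

    wv("stir_t0", bundle.stir_t0)
    wv("stir_t1", bundle.stir_t1)
    wv("t1bone_t0", bundle.t1bone_t0)
    wv("t1bone_t1", bundle.t1bone_t1)
    wv("bone_mask", bundle.bone_mask)
    wv("marrow_ref_mask", bundle.marrow_ref_mask)
    for label, roi in bundle.roi_masks.items():
        wv(f"roi_{label}", roi)
    wv("truth_lesion_t0", bundle.truth.lesion_mask_t0)
    wv("truth_lesion_t1", bundle.truth.lesion_mask_t1)

    sites_df = pd.DataFrame(
        [
            {
                "tooth_id": s.tooth_id,
                "position": s.position,
                "crest_x_mm": s.crest_point[0],
                "crest_y_mm": s.crest_point[1],
                "crest_z_mm": s.crest_point[2],
                "apical_dx": s.apical_dir[0],
                "apical_dy": s.apical_dir[1],
                "apical_dz": s.apical_dir[2],
                "true_depth_t0_mm": bundle.truth.site_depths_t0_mm[i],
                "true_depth_t1_mm": bundle.truth.site_depths_t1_mm[i],
            }
            for i, s in enumerate(bundle.sites)
        ]
    )
    p = os.path.join(out_dir, "sites.csv")
    sites_df.to_csv(p, index=False)
    paths["sites"] = p

    truth = {
        "volume_t0_mm3": bundle.truth.volume_t0_mm3,
        "volume_t1_mm3": bundle.truth.volume_t1_mm3,
        "true_transform": bundle.truth.true_transform.to_dict(),
    }
    p = os.path.join(out_dir, "truth.json")
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["truth"] = p
    return paths


# ---------------------------------------------------------------------------
# clinical site-table simulator

CATEGORIES = ("PPD<=3_noBOP", "PPD<=3_BOP", "PPD4-5", "PPD>=6")


def _default_ppd_dists() -> dict[str, dict[int, float]]:
    return {
        "PPD<=3_noBOP": {1: 0.20, 2: 0.20, 3: 0.60},
        "PPD<=3_BOP": {2: 0.20, 3: 0.80},
        "PPD4-5": {4: 0.60, 5: 0.40},
        "PPD>=6": {6: 0.50, 7: 0.30, 8: 0.15, 9: 0.05},
    }


def _default_ed_t0() -> dict[str, dict[int, float]]:
    # per-stratum baseline ED (mm) among affected sites; medians [IQR]
    # match 2 [1,3] / 1 [1,3] / 1 [1,2] / 2 [2,5]
    return {
        "PPD<=3_noBOP": {1: 0.30, 2: 0.35, 3: 0.20, 4: 0.10, 5: 0.05},
        "PPD<=3_BOP": {1: 0.55, 2: 0.13, 3: 0.17, 4: 0.10, 5: 0.05},
        "PPD4-5": {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08},
        "PPD>=6": {1: 0.20, 2: 0.35, 3: 0.10, 4: 0.09, 5: 0.16, 6: 0.06, 7: 0.04},
    }


def _default_ed_t1() -> dict[str, dict[int, float]]:
    # follow-up ED for sites with baseline edema (mass at 0 = resolved);
    # medians [IQR] match 2 [1,3] / 1 [0,3] / 1 [0,2] / 1 [0,3]
    return {
        "PPD<=3_noBOP": {0: 0.15, 1: 0.20, 2: 0.30, 3: 0.25, 4: 0.10},
        "PPD<=3_BOP": {0: 0.30, 1: 0.30, 2: 0.14, 3: 0.16, 4: 0.10},
        "PPD4-5": {0: 0.30, 1: 0.35, 2: 0.20, 3: 0.15},
        "PPD>=6": {0: 0.30, 1: 0.28, 2: 0.14, 3: 0.18, 4: 0.10},
    }


@dataclass
class ClinicalSimConfig:
    """Configuration of the site-table simulator.

    Category probabilities are over the four baseline PPD strata
    (PPD<=3 without BOP, PPD<=3 with BOP, PPD 4-5, PPD>=6); defaults are
    calibrated so marginal frequencies reproduce the published table
    structure (see module docstring).
    """

    n_patients: int = 35
    teeth_per_patient: int = 5
    sites_per_tooth: int = 6
    n_sites: int | None = None  # truncate to an exact total (e.g. 922)
    category_probs_t0: tuple[float, ...] = (0.342, 0.178, 0.330, 0.150)
    category_probs_t1: tuple[float, ...] = (0.420, 0.150, 0.310, 0.120)
    ppd_within_category_dist: dict[str, dict[int, float]] = field(default_factory=_default_ppd_dists)
    edema_prob_by_category_t0: tuple[float, ...] = (0.18, 0.30, 0.30, 0.92)
    new_edema_prob_t1: float = 0.02
    ed_dist_by_category_t0: dict[str, dict[int, float]] = field(default_factory=_default_ed_t0)
    ed_dist_by_category_t1: dict[str, dict[int, float]] = field(default_factory=_default_ed_t1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (
            ("category_probs_t0", self.category_probs_t0),
            ("category_probs_t1", self.category_probs_t1),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")
            if len(probs) != len(CATEGORIES):
                raise ValueError(f"{name} must have {len(CATEGORIES)} entries")
        for dists in (
            self.ppd_within_category_dist,
            self.ed_dist_by_category_t0,
            self.ed_dist_by_category_t1,
        ):
            for cat, d in dists.items():
                if abs(sum(d.values()) - 1.0) > 1e-9:
                    raise ValueError(f"distribution for {cat} must sum to 1")
        if len(self.edema_prob_by_category_t0) != len(CATEGORIES):
            raise ValueError("edema_prob_by_category_t0 must have 4 entries")

    def to_json(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ClinicalSimConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("ppd_within_category_dist", "ed_dist_by_category_t0", "ed_dist_by_category_t1"):
            if key in d:
                d[key] = {cat: {int(k): v for k, v in dd.items()} for cat, dd in d[key].items()}
        for key in ("category_probs_t0", "category_probs_t1", "edema_prob_by_category_t0"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw(rng: np.random.Generator, dist: dict[int, float], n: int) -> np.ndarray:
    vals = np.array(sorted(dist))
    p = np.array([dist[v] for v in vals], dtype=float)
    p = p / p.sum()
    return rng.choice(vals, size=n, p=p)


def generate_site_table(config: ClinicalSimConfig) -> pd.DataFrame:
    """Simulate a paired baseline/follow-up site table.

    Returns a long-format DataFrame with one row per site per timepoint and
    columns ``patient_id, tooth_id, site_position, timepoint, ppd_mm, bop,
    ed_mm, edema_present``. Site identity (patient, tooth, position) is
    stable across timepoints. Baseline PPD/BOP strata are drawn from
    ``category_probs_t0``; follow-up PPD/BOP are drawn independently from
    ``category_probs_t1`` (the published before/after comparison of category
    counts is unpaired). ED at follow-up is conditioned on the baseline
    stratum of the site, with an explicit probability of resolution.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_patients * config.teeth_per_patient * config.sites_per_tooth
    if config.n_sites is not None:
        if config.n_sites > n_total:
            raise ValueError(
                f"n_sites={config.n_sites} exceeds patients x teeth x sites = {n_total}"
            )
        n_total = config.n_sites
    if n_total == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "tooth_id", "site_position", "timepoint",
                "ppd_mm", "bop", "ed_mm", "edema_present",
            ]
        )

    # site identities
    pat, tooth, pos = [], [], []
    positions = ToothSite.POSITIONS
    i = 0
    for p in range(config.n_patients):
        for t in range(config.teeth_per_patient):
            fdi = 11 + (t % 8) + 10 * (t // 8 % 4)
            for s in range(config.sites_per_tooth):
                if i >= n_total:
                    break
                pat.append(p + 1)
                tooth.append(fdi)
                pos.append(positions[s % 6])
                i += 1
    pat = np.array(pat[:n_total])
    tooth = np.array(tooth[:n_total])
    pos = np.array(pos[:n_total])

    cat0 = rng.choice(len(CATEGORIES), size=n_total, p=np.array(config.category_probs_t0))
    cat1 = rng.choice(len(CATEGORIES), size=n_total, p=np.array(config.category_probs_t1))

    ppd0 = np.zeros(n_total, dtype=int)
    ppd1 = np.zeros(n_total, dtype=int)
    for ci, cname in enumerate(CATEGORIES):
        d = config.ppd_within_category_dist[cname]
        m0 = cat0 == ci
        m1 = cat1 == ci
        if m0.any():
            ppd0[m0] = _draw(rng, d, int(m0.sum()))
        if m1.any():
            ppd1[m1] = _draw(rng, d, int(m1.sum()))
    bop0 = cat0 == 1  # BOP defines the second stratum; deeper strata probed below
    bop1 = cat1 == 1
    # BOP in deeper pockets (not part of the category split): frequencies chosen
    # so overall BOP falls from ~45-49% to ~30% after treatment
    for ci, p_t0, p_t1 in ((2, 0.55, 0.35), (3, 0.85, 0.50)):
        m0 = cat0 == ci
        m1 = cat1 == ci
        bop0 = bop0 | (m0 & (rng.random(n_total) < p_t0))
        bop1 = bop1 | (m1 & (rng.random(n_total) < p_t1))

    # edema at baseline, by baseline stratum
    p_ed0 = np.array(config.edema_prob_by_category_t0)[cat0]
    has_ed0 = rng.random(n_total) < p_ed0
    ed0 = np.zeros(n_total, dtype=float)
    ed1 = np.zeros(n_total, dtype=float)
    for ci, cname in enumerate(CATEGORIES):
        m = has_ed0 & (cat0 == ci)
        if m.any():
            ed0[m] = _draw(rng, config.ed_dist_by_category_t0[cname], int(m.sum()))
            ed1[m] = _draw(rng, config.ed_dist_by_category_t1[cname], int(m.sum()))
    new_ed = ~has_ed0 & (rng.random(n_total) < config.new_edema_prob_t1)
    if new_ed.any():
        ed1[new_ed] = _draw(rng, {1: 0.6, 2: 0.4}, int(new_ed.sum()))

    def frame(tp: str, ppd: np.ndarray, bop: np.ndarray, ed: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": pat,
                "tooth_id": tooth,
                "site_position": pos,
                "timepoint": tp,
                "ppd_mm": ppd,
                "bop": bop.astype(int),
                "ed_mm": ed,
                "edema_present": (ed > 0).astype(int),
            }
        )

    out = pd.concat(
        [frame("t0", ppd0, bop0, ed0), frame("t1", ppd1, bop1, ed1)],
        ignore_index=True,
    )
    return out
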