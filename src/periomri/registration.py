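"""Rigid co-registration of longitudinal volumes.

Follow-up scans are acquired with the head repositioned, so the two
timepoints are related (to good approximation, for bone) by a 6-DOF rigid
transform. This module estimates that transform by deterministic
multi-resolution optimization of an intensity metric and resamples the
follow-up volume into the baseline frame, so that volumes of interest and
linear site measurements refer to identical anatomical positions at both
timepoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .grid import ImageVolume

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "resample",
    "estimate_rigid",
    "target_registration_error",
]


@dataclass
class RigidTransform:
    """A 6-DOF rotation + translation acting on world (mm) coordinates.

    The action is ``p' = R (p - c) + c + t`` with rotation matrix ``R``,
    rotation center ``c`` and translation ``t`` (all mm). Angles are stored
    implicitly in ``rotation``; use :meth:`from_euler` / :meth:`euler_angles`
    for the xyz (extrinsic, radians) parameterization.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation matrix not orthonormal (max dev {err:.2e})")

    # -- construction -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        angles_rad: np.ndarray,
        translation: np.ndarray,
        center: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Build from xyz extrinsic Euler angles (radians) and translation (mm)."""
        rot = Rotation.from_euler("xyz", np.asarray(angles_rad, dtype=float)).as_matrix()
        return cls(rot, translation, np.zeros(3) if center is None else center)

    def euler_angles(self) -> np.ndarray:
        """xyz extrinsic Euler angles (radians) of the rotation part."""
        return Rotation.from_matrix(self.rotation).as_euler("xyz")

    # -- algebra ------------------------------------------------------------

    @property
    def offset(self) -> np.ndarray:
        """Offset ``b`` of the equivalent origin-centered form p' = R p + b."""
        return self.center + self.translation - self.rotation @ self.center

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.offset

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform ``self ∘ other`` (apply ``other`` first)."""
        rot = self.rotation @ other.rotation
        b = self.rotation @ other.offset + self.offset
        # re-express with center 0: t = b when c = 0
        return RigidTransform(rot, b, np.zeros(3))

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        b = -rot @ self.offset
        return RigidTransform(rot, b, np.zeros(3))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "convention": "p' = R(p - c) + c + t; Euler xyz extrinsic, radians; mm",
            "euler_xyz_rad": self.euler_angles().tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_euler(
            np.asarray(d["euler_xyz_rad"]),
            np.asarray(d["translation_mm"]),
            np.asarray(d["center_mm"]),
        )

    @classmethod
    def from_json(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RegistrationResult:
    """Estimated transform plus convergence diagnostics."""

    transform: RigidTransform
    converged: bool
    n_evaluations: int
    final_metric: float
    message: str = ""


_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def resample(
    volume: ImageVolume,
    transform: RigidTransform,
    interpolation: str = "trilinear",
    fill_value: float = 0.0,
) -> ImageVolume:
    """Apply a rigid transform to a volume, resampling on the same grid.

    The output volume lives on the input grid and satisfies
    ``out(x) = in(T^{-1}(x))`` at world point ``x``, i.e. the image content is
    moved by ``transform``. Voxels that map outside the source domain are set
    to ``fill_value``. Use ``nearest`` for label maps/masks and ``trilinear``
    for intensity images.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; expected one of "
            f"{sorted(_INTERP_ORDER)}"
        )
    inv = transform.inverse()
    s = volume.spacing
    o = volume.origin
    # voxel index map: j = S^-1 (R_inv (S i + o) + b_inv - o)
    mat = (inv.rotation * s[np.newaxis, :]) / s[:, np.newaxis]
    off = (inv.rotation @ o + inv.offset - o) / s
    out = ndimage.affine_transform(
        np.asarray(volume.data, dtype=float),
        mat,
        offset=off,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=fill_value,
        prefilter=False,
    )
    if interpolation == "nearest":
        out = out.astype(volume.data.dtype)
    return volume.like(out)


def target_registration_error(
    t_true: RigidTransform, t_est: RigidTransform, points: np.ndarray
) -> float:
    """Mean Euclidean distance (mm) between t_true(p) and t_est(p)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("target_registration_error requires at least one point")
    d = np.linalg.norm(t_true.apply(points) - t_est.apply(points), axis=-1)
    return float(d.mean())


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def _border_median(data: np.ndarray) -> float:
    faces = [data[0], data[-1], data[:, 0], data[:, -1], data[:, :, 0], data[:, :, -1]]
    return float(np.median(np.concatenate([f.ravel() for f in faces])))


def _metric(fixed: np.ndarray, moved: np.ndarray, kind: str) -> float:
    if kind == "msd":
        return float(np.mean((fixed - moved) ** 2))
    if kind == "ncc":  # negative Pearson correlation, for cross-contrast pairs
        f = fixed - fixed.mean()
        m = moved - moved.mean()
        denom = np.sqrt((f**2).sum() * (m**2).sum())
        if denom == 0:
            return 0.0
        return -float((f * m).sum() / denom)
    raise ValueError(f"unknown similarity metric {kind!r}")


def estimate_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    metric: str = "msd",
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter: int = 60,
    xtol: float = 1e-4,
    ftol: float = 1e-8,
    initial: RigidTransform | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` into ``fixed``'s frame.

    Deterministic multi-resolution Powell descent over the 6 rigid parameters
    (3 Euler angles, 3 translations), with the rotation center at the fixed
    volume's geometric center. The similarity metric is the mean squared
    intensity difference (``msd``, default, for same-contrast pairs) or
    negative correlation (``ncc``, for cross-contrast pairs). All schedules
    are fixed and no stochastic sampling is used, so the result is
    reproducible given identical inputs and options.

    Returns a :class:`RegistrationResult`; ``result.transform`` maps moving
    world coordinates into the fixed frame, i.e.
    ``resample(moving, result.transform)`` aligns with ``fixed``.
    """
    if not fixed.same_grid(moving):
        raise ValueError("fixed and moving must share a grid (resample first)")
    if metric not in ("msd", "ncc"):
        raise ValueError(f"unknown similarity metric {metric!r}")

    center = fixed.index_to_world((np.array(fixed.shape) - 1) / 2.0)
    fill = _border_median(np.asarray(moving.data, dtype=float))
    fdat = np.asarray(fixed.data, dtype=float)
    mdat = np.asarray(moving.data, dtype=float)

    if initial is not None:
        ang0 = np.degrees(initial.euler_angles())
        # re-center the initial transform at our rotation center
        b = initial.offset
        t0 = initial.rotation @ center + b - center
        params = np.concatenate([ang0, t0])
    else:
        params = np.zeros(6)

    n_eval = 0
    converged = True
    message = ""
    for factor in levels:
        f_lo = _downsample(fdat, factor)
        m_lo = _downsample(mdat, factor)
        vol_lo = ImageVolume(m_lo, moving.spacing * factor, moving.origin)
        fix_lo = ImageVolume(f_lo, fixed.spacing * factor, fixed.origin)
        if not np.any(np.isfinite(f_lo)):
            raise ValueError("fixed volume has no finite voxels at this level")

        def cost(p: np.ndarray) -> float:
            tr = RigidTransform.from_euler(np.radians(p[:3]), p[3:], center)
            moved = resample(vol_lo, tr, "trilinear", fill_value=fill)
            return _metric(fix_lo.data, moved.data, metric)

        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options={"maxiter": maxiter, "xtol": xtol, "ftol": ftol},
        )
        params = res.x
        n_eval += int(res.nfev)
        if not res.success:
            converged = False
            message = str(res.message)

    transform = RigidTransform.from_euler(np.radians(params[:3]), params[3:], center)
    final = _metric(
        fdat, resample(moving, transform, "trilinear", fill_value=fill).data, metric
    )
    if not converged:
        warnings.warn(f"rigid registration did not fully converge: {message}")
    return RegistrationResult(transform, converged, n_eval, final, message)
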