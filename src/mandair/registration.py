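"""Rigid superimposition and the skull-aligned coordinate frame.

Pre- and post-operative bone meshes are superimposed on surgically unchanged
cranial anatomy with masked iterative-closest-point (ICP) alignment; all
positional deviations are then expressed in a cranial frame built from named
landmarks (X anterior, Y left-lateral, Z cranial, right-handed).

Because the alignment mask must exclude the surgical site, ``register_icp``
takes an explicit region (box/sphere in scan coordinates, or a mesh whose
bounding box is used).  Correspondences are closest points on the fixed
surface, computed exactly per triangle; sampling of the moving surface is
seeded, so registration is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    ConvergenceError,
    DegenerateFrameError,
    InsufficientDataError,
    ValidationError,
)
from .mesh_core import Plane, RegionSpec, SurfaceMesh, crop_faces

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(r @ r.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(f"rotation not orthonormal (|R Rᵀ - I| = {err:.2e})")
        if err > 1e-12:  # re-project slightly drifted rotations
            u, _, vt = np.linalg.svd(r)
            r = u @ vt
        if np.linalg.det(r) < 0:
            raise ValidationError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        return mesh.transformed(self.rotation, self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(np.asarray(json.loads(text)["matrix"]))


# ---------------------------------------------------------------------------
# cranial frame and landmarks
# ---------------------------------------------------------------------------

REQUIRED_LANDMARKS = ("origin", "anterior", "axial_a", "axial_b", "axial_c")


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D landmarks (mm) driving frame construction.

    Required names: ``origin`` (frame origin), ``anterior`` (a point anterior
    of the origin fixing the X direction), and the axial triple ``axial_a``,
    ``axial_b``, ``axial_c`` whose plane defines the axial plane.  The triple
    is ordered so that ``(b - a) x (c - a)`` points cranially.
    """

    points: dict

    def __post_init__(self):
        pts = {k: np.asarray(v, float).reshape(3) for k, v in self.points.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in pts]
        if missing:
            raise ValidationError(f"missing landmarks: {missing}")
        names = list(pts)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.linalg.norm(pts[a] - pts[b]) < 0.1:
                    raise ValidationError(
                        f"landmarks {a!r} and {b!r} coincide within 0.1 mm"
                    )
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: transform.apply(v) for k, v in self.points.items()})

    def to_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.points.items()}


@dataclass(frozen=True)
class CranialFrame:
    """Right-handed skull frame: X anterior, Y left-lateral, Z cranial."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, float).reshape(3)
        axes = [np.asarray(a, float).reshape(3) for a in (self.axis_x, self.axis_y, self.axis_z)]
        basis = np.asarray(axes)
        if np.abs(basis @ basis.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("frame axes not orthonormal")
        if np.abs(np.cross(axes[0], axes[1]) - axes[2]).max() > 1e-9:
            raise ValidationError("frame is not right-handed (x × y ≠ z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axis_x", axes[0])
        object.__setattr__(self, "axis_y", axes[1])
        object.__setattr__(self, "axis_z", axes[2])

    @classmethod
    def canonical(cls) -> "CranialFrame":
        return cls(np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])

    @property
    def basis(self) -> np.ndarray:
        """Rows are the frame axes (world -> frame rotation)."""
        return np.vstack([self.axis_x, self.axis_y, self.axis_z])


def build_frame(landmarks: LandmarkSet) -> CranialFrame:
    """Construct the cranial frame from landmarks.

    Z is the unit normal of the axial triple (oriented cranially by the
    triple's ordering convention); X is the anterior direction projected
    orthogonal to Z; Y = Z x X (left-lateral); origin at the ``origin``
    landmark.
    """
    a, b, c = (landmarks[k] for k in ("axial_a", "axial_b", "axial_c"))
    n = np.cross(b - a, c - a)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a))
    if np.linalg.norm(n) < 1e-9 * max(scale**2, 1.0):
        raise DegenerateFrameError("axial landmark triple is collinear")
    z = n / np.linalg.norm(n)
    ant = landmarks["anterior"] - landmarks["origin"]
    x = ant - (ant @ z) * z
    if np.linalg.norm(x) < 1e-9:
        raise DegenerateFrameError("anterior landmark is parallel to the axial normal")
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return CranialFrame(landmarks["origin"], x, y, z)


def to_frame(obj, frame: CranialFrame):
    """Express a mesh or point in frame coordinates (rigid change of basis)."""
    basis = frame.basis
    if isinstance(obj, SurfaceMesh):
        return SurfaceMesh((obj.vertices - frame.origin) @ basis.T, obj.faces.copy(), obj.name)
    pts = np.asarray(obj, float)
    return (pts - frame.origin) @ basis.T


def from_frame(obj, frame: CranialFrame):
    """Inverse of :func:`to_frame`."""
    basis = frame.basis
    if isinstance(obj, SurfaceMesh):
        return SurfaceMesh(obj.vertices @ basis + frame.origin, obj.faces.copy(), obj.name)
    pts = np.asarray(obj, float)
    return pts @ basis + frame.origin


def midsagittal_plane(frame: CranialFrame) -> Plane:
    """The XZ plane of the frame (normal = left-lateral Y axis)."""
    return Plane(frame.origin, frame.axis_y)


# ---------------------------------------------------------------------------
# closest-point queries and ICP
# ---------------------------------------------------------------------------


class _SurfaceIndex:
    """Exact closest-point-on-surface queries against a fixed mesh.

    Candidate faces come from a KD-tree over face centroids; the exact
    point-triangle projection is then evaluated on the candidates.
    """

    def __init__(self, tm: trimesh.Trimesh, k: int = 8):
        self.triangles = np.asarray(tm.triangles, float)
        self.tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.triangles))

    def query(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        _, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        cand = self.triangles[idx.ravel()]
        rep = np.repeat(pts, self.k, axis=0)
        closest = trimesh.triangles.closest_point(cand, rep)
        d2 = ((closest - rep) ** 2).sum(axis=1).reshape(len(pts), self.k)
        best = d2.argmin(axis=1)
        return closest.reshape(len(pts), self.k, 3)[np.arange(len(pts)), best]


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``."""
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    h = (src - c_src).T @ (dst - c_dst)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, c_dst - r @ c_src)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool
    rms_trace: list = field(default_factory=list)


def register_icp(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    mask_region: RegionSpec | SurfaceMesh | None = None,
    init: RigidTransform | None = None,
    samples: int = 2000,
    seed: int = 0,
    max_iterations: int = 1000,
    tol: float = 1e-10,
    patience: int = 10,
) -> RegistrationResult:
    """Masked rigid ICP alignment of ``moving`` onto ``fixed``.

    Correspondences are exact closest points on the fixed surface from a
    seeded uniform sample of the moving surface.  Convergence: relative RMS
    change below ``tol``, RMS below 1e-10 mm, or ``max_iterations``
    (point-to-point ICP converges linearly, so noise-free alignment to
    sub-0.01° needs several hundred cheap iterations).  Divergence (RMS persistently
    above 1.5x its running minimum for ``patience`` iterations) raises
    :class:`ConvergenceError` carrying the iteration trace.
    """
    if mask_region is not None:
        if isinstance(mask_region, SurfaceMesh):
            lo, hi = mask_region.to_trimesh().bounds
            pad = 0.05 * np.linalg.norm(hi - lo)
            mask_region = RegionSpec("box", bounds=(tuple(lo - pad), tuple(hi + pad)))
        moving_m = crop_faces(moving, mask_region)
        fixed_m = crop_faces(fixed, mask_region)
    else:
        moving_m, fixed_m = moving, fixed

    if moving_m.n_vertices < 100 or fixed_m.n_vertices < 100:
        raise InsufficientDataError(
            f"insufficient masked points for registration "
            f"(moving {moving_m.n_vertices}, fixed {fixed_m.n_vertices}; need ≥ 100)"
        )

    tm_moving = moving_m.to_trimesh()
    tm_fixed = fixed_m.to_trimesh()
    n_samples = min(samples, 4 * len(tm_moving.faces))
    src0, _ = trimesh.sample.sample_surface(tm_moving, n_samples, seed=seed)
    src0 = np.asarray(src0, float)

    if init is None:
        init = RigidTransform(
            np.eye(3), np.asarray(tm_fixed.centroid) - np.asarray(tm_moving.centroid)
        )
    total = init
    index = _SurfaceIndex(tm_fixed)

    trace: list[float] = []
    best_rms = np.inf
    best_iter = 0
    prev_rms = None
    converged = False
    for iteration in range(max_iterations):
        src = total.apply(src0)
        dst = index.query(src)
        rms = float(np.sqrt(((dst - src) ** 2).sum(axis=1).mean()))
        trace.append(rms)
        if rms < best_rms:
            best_rms, best_iter = rms, iteration
        elif rms > 1.5 * max(best_rms, 1e-12) and iteration - best_iter >= patience:
            raise ConvergenceError(
                f"ICP diverged: RMS {rms:.4g} vs best {best_rms:.4g} "
                f"at iteration {iteration}",
                trace=trace,
            )
        if rms < 1e-10:
            converged = True
            break
        if prev_rms is not None and abs(prev_rms - rms) <= tol * max(prev_rms, 1e-12):
            converged = True
            break
        prev_rms = rms
        total = _kabsch(src, dst).compose(total)

    return RegistrationResult(
        transform=total,
        rms=trace[-1],
        n_iterations=len(trace),
        converged=converged,
        rms_trace=trace,
    )
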