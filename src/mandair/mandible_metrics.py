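"""Condylar and symphyseal positional change in the cranial frame.

Condyles are assumed rigid: the best-fit rigid transform between the pre- and
post-operative condylar region meshes encodes the pose change, which is then
reported as signed axis deviations (dX, dY, dZ), in-plane deviation magnitudes
(dXY, dXZ, dYZ), the Euclidean deviation dXYZ, and rotations Phi(X), Theta(Y),
Psi(Z) about the frame axes.

Euler convention: intrinsic X-Y-Z (R = Rx(phi) · Ry(theta) · Rz(psi)), fixed
and regression-tested.  At gimbal lock (|theta| = 90°) phi is set to 0 and the
coupled angle folded into psi; the output is flagged.

The symphysis (often replaced by fibular bone, so of different shape pre vs
post) is compared via the area centroid S of its intersection with the
midsagittal plane: S_dX and S_dZ are the signed centroid differences
(post - pre) on the frame X and Z axes, S_dXZ their 2D norm.  A negative S_dX
is a posterior (setback-like) shift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import EmptyContourError
from .mesh_core import Plane, RegionSpec, SurfaceMesh, contour_centroid, crop_faces, section_with_plane
from .registration import CranialFrame, RegistrationResult, RigidTransform, register_icp

log = logging.getLogger(__name__)

GIMBAL_TOL_DEG = 1e-6


@dataclass(frozen=True)
class CondyleDisplacement:
    """Rigid pose change of one condyle, resolved on the cranial frame."""

    side: Literal["left", "right"]
    dX: float
    dY: float
    dZ: float
    dXY: float
    dXZ: float
    dYZ: float
    dXYZ: float
    phi_x: float
    theta_y: float
    psi_z: float
    gimbal_lock: bool = False

    def as_dict(self) -> dict:
        return {
            "side": self.side,
            "dX": self.dX,
            "dY": self.dY,
            "dZ": self.dZ,
            "dXY": self.dXY,
            "dXZ": self.dXZ,
            "dYZ": self.dYZ,
            "dXYZ": self.dXYZ,
            "phi_x": self.phi_x,
            "theta_y": self.theta_y,
            "psi_z": self.psi_z,
        }


@dataclass(frozen=True)
class SymphysisDeviation:
    """Deviation of the symphysis midsagittal-section centre point S."""

    s_dx: float
    s_dz: float
    s_dxz: float
    centre_pre: np.ndarray
    centre_post: np.ndarray

    def as_dict(self) -> dict:
        return {"S_dX": self.s_dx, "S_dZ": self.s_dz, "S_dXZ": self.s_dxz}


def crop_region(mesh: SurfaceMesh, region_spec: RegionSpec, name: str = "") -> SurfaceMesh:
    """Sub-mesh of faces whose centroids fall inside the region (box or
    sphere in frame coordinates)."""
    return crop_faces(mesh, region_spec, name=name)


def fit_region_transform(
    region_pre: SurfaceMesh,
    region_post: SurfaceMesh,
    shape_change_rms: float = 0.5,
    seed: int = 0,
    samples: int = 2000,
) -> RegistrationResult:
    """Best-fit rigid transform mapping the pre-operative region mesh onto the
    post-operative one (ICP with centroid initialisation).

    A final RMS above ``shape_change_rms`` mm logs a warning: the rigid
    assumption (unchanged condylar shape) is then questionable, e.g. for a
    remodelled or resected condyle.
    """
    result = register_icp(region_pre, region_post, seed=seed, samples=samples)
    if result.rms > shape_change_rms:
        log.warning(
            "region %r vs %r: residual RMS %.3f mm exceeds %.3f mm — "
            "rigid-shape assumption may be violated",
            region_pre.name,
            region_post.name,
            result.rms,
            shape_change_rms,
        )
    return result


def _euler_intrinsic_xyz(r: np.ndarray) -> tuple[float, float, float, bool]:
    """Decompose R = Rx(phi) @ Ry(theta) @ Rz(psi); angles in degrees.

    At gimbal lock phi is fixed to 0 and the residual rotation folded into
    psi; returns (phi, theta, psi, gimbal_flag).
    """
    s = float(np.clip(r[0, 2], -1.0, 1.0))
    theta = math.degrees(math.asin(s))
    if 90.0 - abs(theta) < GIMBAL_TOL_DEG:
        # R = Rx(0) @ Ry(±90) @ Rz(psi)  =>  Rz(psi) = Ry(∓90) @ R
        c, sn = 0.0, math.copysign(1.0, s)
        ry_inv = np.array([[c, 0.0, -sn], [0.0, 1.0, 0.0], [sn, 0.0, c]])
        rz = ry_inv @ r
        psi = math.degrees(math.atan2(rz[1, 0], rz[0, 0]))
        return 0.0, theta, psi, True
    phi = math.degrees(math.atan2(-r[1, 2], r[2, 2]))
    psi = math.degrees(math.atan2(-r[0, 1], r[0, 0]))
    return phi, theta, psi, False


def condyle_displacement(
    transform: RigidTransform,
    reference_point: np.ndarray,
    side: Literal["left", "right"],
    frame: CranialFrame | None = None,
) -> CondyleDisplacement:
    """Resolve a condylar pose change into the Euclidean/axis/plane deviation
    metrics and the Euler rotations.

    ``reference_point`` is the area-weighted centroid of the pre-operative
    condylar region; its displacement under ``transform`` gives the signed
    axis deviations.  ``frame`` defaults to the canonical frame (use after
    :func:`mandair.registration.to_frame`).
    """
    if frame is None:
        frame = CranialFrame.canonical()
    ref = np.asarray(reference_point, float).reshape(3)
    d_world = transform.apply(ref) - ref
    d = frame.basis @ d_world
    dx, dy, dz = (float(v) for v in d)
    # rotation part expressed on the frame axes
    r_frame = frame.basis @ transform.rotation @ frame.basis.T
    phi, theta, psi, gimbal = _euler_intrinsic_xyz(r_frame)
    if gimbal:
        log.warning("condyle %s: gimbal-lock configuration; phi_x set to 0", side)
    return CondyleDisplacement(
        side=side,
        dX=dx,
        dY=dy,
        dZ=dz,
        dXY=math.hypot(dx, dy),
        dXZ=math.hypot(dx, dz),
        dYZ=math.hypot(dy, dz),
        dXYZ=float(np.linalg.norm(d)),
        phi_x=phi,
        theta_y=theta,
        psi_z=psi,
        gimbal_lock=gimbal,
    )


def symphysis_deviation(
    pre_mesh: SurfaceMesh,
    post_mesh: SurfaceMesh,
    plane: Plane,
    frame: CranialFrame | None = None,
) -> SymphysisDeviation:
    """Centre-point deviation of the symphysis in the midsagittal plane.

    Both meshes are sectioned with ``plane``; the area centroids of the
    enclosed regions are differenced (post - pre) on the frame X and Z axes.
    """
    if frame is None:
        frame = CranialFrame.canonical()
    try:
        c_pre = contour_centroid(section_with_plane(pre_mesh, plane))
        c_post = contour_centroid(section_with_plane(post_mesh, plane))
    except EmptyContourError as exc:
        raise EmptyContourError(
            f"symphysis not restored at the midline: {exc}"
        ) from exc
    diff = c_post - c_pre
    s_dx = float(diff @ frame.axis_x)
    s_dz = float(diff @ frame.axis_z)
    return SymphysisDeviation(
        s_dx=s_dx,
        s_dz=s_dz,
        s_dxz=math.hypot(s_dx, s_dz),
        centre_pre=c_pre,
        centre_post=c_post,
    )
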