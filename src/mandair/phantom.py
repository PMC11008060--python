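"""Synthetic ground-truth phantoms for end-to-end validation.

Real pre/post CT mesh pairs are not distributable, so validation runs on
schematic phantoms with exactly known ground truth: a spherical "skull"
shell (the registration anchor, unchanged by surgery), two condyle blobs
(asymmetrically deformed ellipsoids, so their pose is uniquely recoverable),
a symphyseal arch (a capped partial torus whose midsagittal section is an
exact circle with analytically known centre), and an airway lumen built as a
tube of revolution along the cranial axis with a controllable radius profile.

Post-operative meshes are the pre-operative meshes with known per-region
rigid transforms applied; the phantom emits landmarks, region/mask
configuration and the truth table, so generated cases are indistinguishable
from real inputs to the measurement pipeline.

The cohort generator draws a per-subject sagittal symphysis shift and couples
the post-operative airway waist to it through a Gaussian copula with a
monotone link, so the population Spearman correlation between the shift and
the hypopharyngeal minCSA percentage change equals the requested coupling in
expectation (rank correlation of a bivariate normal: rho_s = (6/pi)
asin(rho_p / 2), inverted in closed form).

All randomness flows from explicit integer seeds; a fixed seed reproduces
byte-identical meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .errors import ValidationError
from .airway_metrics import AirwayPlanes
from .mesh_core import RegionSpec, SurfaceMesh, _cap_boundary_loops
from .registration import LandmarkSet, RigidTransform
from scipy.spatial.transform import Rotation as _Rotation

# ---------------------------------------------------------------------------
# template geometry (mm, in the canonical cranial frame)
# ---------------------------------------------------------------------------

# The layout is schematic, not anatomical: parts are spaced so that every
# region crop box keeps >= 20 mm of translation headroom around its part
# without ever touching another part.
SKULL_CENTER = np.array([0.0, 0.0, 80.0])
SKULL_RADIUS = 50.0
CONDYLE_CENTERS = {"left": np.array([-45.0, 45.0, -15.0]), "right": np.array([-45.0, -45.0, -15.0])}
CONDYLE_SEMI_AXES = (9.0, 7.0, 12.0)
ARCH_CENTER = np.array([0.0, 0.0, -45.0])
ARCH_MAJOR_RADIUS = 45.0
ARCH_TUBE_RADIUS = 7.0
ARCH_SPAN_DEG = 120.0

#: airway reference-plane Z offsets (top, naso/oro, E-plane, bottom)
AIRWAY_PLANE_Z = {"top": 30.0, "naso_oro": 10.0, "e_plane": -10.0, "bottom": -40.0}
TUBE_Z_RANGE = (-45.5, 35.5)

LANDMARKS = {
    "origin": (0.0, 0.0, 0.0),
    "anterior": (90.0, 0.0, 0.0),
    "axial_a": (50.0, 0.0, 0.0),
    "axial_b": (-50.0, 30.0, 0.0),
    "axial_c": (-50.0, -30.0, 0.0),
}

MASK_REGION = RegionSpec("sphere", center=tuple(SKULL_CENTER), radius=SKULL_RADIUS + 2.0)
REGION_SPECS = {
    "condyle_left": RegionSpec("box", bounds=((-85.0, 5.0, -55.0), (-5.0, 85.0, 25.0))),
    "condyle_right": RegionSpec("box", bounds=((-85.0, -85.0, -55.0), (-5.0, -5.0, 25.0))),
    "symphysis": RegionSpec("box", bounds=((10.0, -25.0, -75.0), (70.0, 25.0, -18.0))),
}


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiusProfile:
    """Airway tube radius as a function of offset from the E-plane [mm].

    A baseline radius ``r0`` with an optional Gaussian waist of minimum
    radius ``waist_min`` centred at ``waist_center`` with width
    ``waist_width`` (standard deviation of the Gaussian dip).
    """

    r0: float = 6.0
    waist_min: float | None = 4.5
    waist_center: float = -15.0
    waist_width: float = 6.0

    def __call__(self, offsets) -> np.ndarray:
        o = np.asarray(offsets, float)
        r = np.full_like(o, self.r0)
        if self.waist_min is not None:
            dip = (self.r0 - self.waist_min) * np.exp(
                -((o - self.waist_center) ** 2) / (2.0 * self.waist_width**2)
            )
            r = r - dip
        if np.any(r <= 0):
            raise ValidationError("radius profile must be strictly positive")
        return r


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one synthetic case.

    Condyle transforms are given as intrinsic X-Y-Z Euler rotations [deg] and
    translations [mm] of the condyle's own surface centroid; the symphysis
    shift is (s_dx, s_dz) in the midsagittal plane.
    """

    condyle_left_rot: tuple = (0.0, 0.0, 0.0)
    condyle_left_trans: tuple = (0.0, 0.0, 0.0)
    condyle_right_rot: tuple = (0.0, 0.0, 0.0)
    condyle_right_trans: tuple = (0.0, 0.0, 0.0)
    symphysis_shift: tuple = (0.0, 0.0)
    pre_profile: RadiusProfile = field(default_factory=RadiusProfile)
    post_profile: RadiusProfile = field(default_factory=RadiusProfile)
    noise_sd: float = 0.0
    seed: int = 0
    segments: int = 128
    ring_spacing: float = 1.0
    label: str = "phantom"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def condyle_rotation(self, side: str) -> tuple:
        return getattr(self, f"condyle_{side}_rot")

    def condyle_translation(self, side: str) -> tuple:
        return getattr(self, f"condyle_{side}_trans")


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort generator settings.

    Defaults emulate the reconstruction-cohort conditions: 35 subjects, a
    predominantly posterior (negative X) symphysis shift of several mm, a
    hypopharyngeal minCSA change with median slightly below 100%, and small
    residual condylar pose changes.
    """

    n: int = 35
    coupling: float = 0.9
    setback_loc: float = -7.0
    setback_scale: float = 4.0
    sdz_scale: float = 2.0
    nuisance_sd: float = 0.0
    mincsa_log_loc: float = -0.105
    mincsa_log_scale: float = 0.2
    condyle_rot_sd: float = 3.0
    condyle_trans_sd: float = 1.5
    seed: int = 0
    segments: int = 64
    ring_spacing: float = 1.0

    def __post_init__(self):
        if abs(self.coupling) > 1:
            raise ValidationError("|coupling| must be <= 1")
        if self.n < 4:
            raise ValidationError("cohort needs n >= 4")
        if self.nuisance_sd < 0:
            raise ValidationError("nuisance_sd must be >= 0")


# ---------------------------------------------------------------------------
# mesh part builders
# ---------------------------------------------------------------------------


def _grid_faces(nu: int, nv: int, wrap_v: bool) -> np.ndarray:
    """Quad-grid triangulation for a (nu x nv) vertex grid."""
    faces = []
    for i in range(nu - 1):
        for j in range(nv if wrap_v else nv - 1):
            j2 = (j + 1) % nv
            a, b = i * nv + j, i * nv + j2
            c, d = (i + 1) * nv + j, (i + 1) * nv + j2
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=np.int64)


def _closed_from_open(vertices: np.ndarray, faces: np.ndarray, name: str) -> SurfaceMesh:
    """Cap the open boundaries of a surface grid and orient outward."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    tm = _cap_boundary_loops(tm)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh.from_trimesh(tm, name)


def tube_mesh(
    z_values: np.ndarray, radii: np.ndarray, segments: int = 128, name: str = "tube"
) -> SurfaceMesh:
    """Watertight tube of revolution along Z with per-ring radii."""
    z = np.asarray(z_values, float)
    r = np.asarray(radii, float)
    if np.any(r <= 0):
        raise ValidationError("tube radii must be strictly positive")
    theta = 2 * np.pi * np.arange(segments) / segments
    ct, st = np.cos(theta), np.sin(theta)
    verts = np.concatenate(
        [np.column_stack((ri * ct, ri * st, np.full(segments, zi))) for zi, ri in zip(z, r)]
    )
    faces = _grid_faces(len(z), segments, wrap_v=True)
    return _closed_from_open(verts, faces, name)


def skull_shell(subdivisions: int = 3) -> SurfaceMesh:
    """Spherical cranium stand-in (the superimposition anchor)."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=SKULL_RADIUS)
    return SurfaceMesh(tm.vertices + SKULL_CENTER, tm.faces, "skull")


def condyle(side: str, subdivisions: int = 3) -> SurfaceMesh:
    """Condylar blob: an ellipsoid with a mild asymmetric taper.

    The taper removes the ellipsoid's 180° self-symmetries so the rigid pose
    recovered by registration is unique.
    """
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(tm.vertices, float)
    a, b, c = CONDYLE_SEMI_AXES
    w = np.column_stack(
        [
            a * u[:, 0] * (1.0 + 0.25 * u[:, 2]),
            b * u[:, 1] * (1.0 + 0.25 * u[:, 0]),
            c * u[:, 2],
        ]
    )
    return SurfaceMesh(w + CONDYLE_CENTERS[side], tm.faces, f"condyle_{side}")


def symphysis_arch(
    nu: int = 49, nv: int = 32, span_deg: float = ARCH_SPAN_DEG
) -> SurfaceMesh:
    """Capped partial torus representing the anterior mandibular arch.

    Its intersection with the midsagittal plane (y = 0) is the exact tube
    circle at the arch apex, whose area centroid is (major radius, 0,
    arch-centre z) — an analytic truth for the centre-point measurement.
    """
    half = math.radians(span_deg / 2.0)
    u = np.linspace(-half, half, nu)
    v = 2 * np.pi * np.arange(nv) / nv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    ring = ARCH_MAJOR_RADIUS + ARCH_TUBE_RADIUS * np.cos(vv)
    verts = np.column_stack(
        [
            (ring * np.cos(uu)).ravel(),
            (ring * np.sin(uu)).ravel(),
            (ARCH_TUBE_RADIUS * np.sin(vv)).ravel(),
        ]
    )
    faces = _grid_faces(nu, nv, wrap_v=True)
    mesh = _closed_from_open(verts + ARCH_CENTER, faces, "symphysis")
    return mesh


def make_region_transform(
    rotation_deg, translation, about
) -> RigidTransform:
    """Rigid transform rotating by intrinsic X-Y-Z Euler angles about a pivot
    point, then translating; the pivot is displaced exactly by
    ``translation``."""
    r = _Rotation.from_euler("XYZ", rotation_deg, degrees=True).as_matrix()
    about = np.asarray(about, float)
    t = np.asarray(translation, float) + about - r @ about
    return RigidTransform(r, t)


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------


@dataclass
class BonePhantom:
    pre: SurfaceMesh
    post: SurfaceMesh
    landmarks: LandmarkSet
    parts_pre: dict
    parts_post: dict
    condyle_transforms: dict
    mask_region: RegionSpec
    region_specs: dict
    truth: PhantomTruth


@dataclass
class AirwayPhantom:
    pre: SurfaceMesh
    post: SurfaceMesh
    planes: AirwayPlanes
    truth: PhantomTruth


def _add_noise(mesh: SurfaceMesh, sd: float, rng: np.random.Generator) -> SurfaceMesh:
    if sd <= 0:
        return mesh
    return SurfaceMesh(
        mesh.vertices + rng.normal(0.0, sd, mesh.vertices.shape), mesh.faces, mesh.name
    )


def make_bone_phantom(truth: PhantomTruth, subdivisions: int = 3) -> BonePhantom:
    """Pre/post bone mesh pair (skull shell + condyles + symphysis arch)
    under the truth's per-region transforms, plus landmarks and configuration.

    The skull shell is identical at both time points (the registration
    anchor); optional vertex noise is applied independently per time point.
    """
    rng = np.random.default_rng(truth.seed)
    skull = skull_shell(subdivisions)
    arch = symphysis_arch()
    parts_pre = {"skull": skull, "symphysis": arch}
    parts_post = {"skull": skull}
    transforms = {}
    for side in ("left", "right"):
        pre_c = condyle(side, subdivisions)
        parts_pre[f"condyle_{side}"] = pre_c
        t = make_region_transform(
            truth.condyle_rotation(side),
            truth.condyle_translation(side),
            about=pre_c.surface_centroid(),
        )
        transforms[side] = t
        parts_post[f"condyle_{side}"] = t.apply_mesh(pre_c)
    s_dx, s_dz = truth.symphysis_shift
    parts_post["symphysis"] = arch.transformed(np.eye(3), np.array([s_dx, 0.0, s_dz]))

    order = ("skull", "condyle_left", "condyle_right", "symphysis")
    pre = parts_pre[order[0]].concatenated(*[parts_pre[k] for k in order[1:]], name="bone_pre")
    post = parts_post[order[0]].concatenated(*[parts_post[k] for k in order[1:]], name="bone_post")
    pre = _add_noise(pre, truth.noise_sd, rng)
    post = _add_noise(post, truth.noise_sd, rng)
    return BonePhantom(
        pre=pre,
        post=post,
        landmarks=LandmarkSet(dict(LANDMARKS)),
        parts_pre=parts_pre,
        parts_post=parts_post,
        condyle_transforms=transforms,
        mask_region=MASK_REGION,
        region_specs=dict(REGION_SPECS),
        truth=truth,
    )


def airway_planes() -> AirwayPlanes:
    z = AIRWAY_PLANE_Z
    return AirwayPlanes.from_z_offsets(z["top"], z["naso_oro"], z["e_plane"], z["bottom"])


def make_airway_phantom(truth: PhantomTruth) -> AirwayPhantom:
    """Pre/post airway lumen tubes with the truth's radius profiles.

    Rings sit at half-multiples of ``ring_spacing`` so the integer profile
    offsets never coincide with a vertex ring.  The truth's vertex noise is
    not applied to the lumen: it emulates bone-segmentation jitter, and the
    airway truth is the exactly controlled radius profile.
    """
    z_lo, z_hi = TUBE_Z_RANGE
    n = int(round((z_hi - z_lo) / truth.ring_spacing)) + 1
    z = z_lo + truth.ring_spacing * np.arange(n)
    e_z = AIRWAY_PLANE_Z["e_plane"]
    meshes = {}
    for tag, profile in (("pre", truth.pre_profile), ("post", truth.post_profile)):
        radii = profile(z - e_z)
        meshes[tag] = tube_mesh(z, radii, segments=truth.segments, name=f"airway_{tag}")
    return AirwayPhantom(
        pre=meshes["pre"], post=meshes["post"], planes=airway_planes(), truth=truth
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation yielding rank correlation rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def attainable_coupling(nuisance_sd: float) -> float:
    """Largest |Spearman coupling| reachable at the given nuisance scale."""
    rho_p_max = 1.0 / math.sqrt(1.0 + nuisance_sd**2)
    return (6.0 / math.pi) * math.asin(rho_p_max / 2.0)


def make_cohort(spec: CohortSpec) -> tuple[list[PhantomTruth], pd.DataFrame]:
    """Draw a cohort of per-subject truths plus the expected-truth table.

    The sagittal symphysis shift s_dx and the latent driving the
    post-operative waist radius are jointly Gaussian; the waist link is
    monotone, so the population Spearman correlation between s_dx and the
    hypopharyngeal minCSA percentage change equals ``spec.coupling``.
    Independent nuisance noise (scale ``nuisance_sd``) attenuates the
    correlation; the generator compensates exactly and raises if the target
    is unattainable.
    """
    rho_p = _pearson_for_spearman(spec.coupling)
    rho_lat = rho_p * math.sqrt(1.0 + spec.nuisance_sd**2)
    if abs(rho_lat) > 1.0:
        raise ValidationError(
            f"coupling {spec.coupling} unattainable with nuisance_sd "
            f"{spec.nuisance_sd}; attainable |coupling| <= "
            f"{attainable_coupling(spec.nuisance_sd):.3f}"
        )
    rng = np.random.default_rng(spec.seed)
    z1 = rng.normal(size=spec.n)
    z2_raw = rho_lat * z1 + math.sqrt(1.0 - rho_lat**2) * rng.normal(size=spec.n)
    z2 = (z2_raw + spec.nuisance_sd * rng.normal(size=spec.n)) / math.sqrt(
        1.0 + spec.nuisance_sd**2
    )
    s_dx = spec.setback_loc + spec.setback_scale * z1
    s_dz = spec.sdz_scale * rng.normal(size=spec.n)
    pct_true = 100.0 * np.exp(spec.mincsa_log_loc + spec.mincsa_log_scale * z2)
    pct_true = np.clip(pct_true, 30.0, 250.0)

    template = RadiusProfile()
    truths: list[PhantomTruth] = []
    rows = []
    for i in range(spec.n):
        waist_post = template.waist_min * math.sqrt(pct_true[i] / 100.0)
        if waist_post >= template.r0:
            waist_post = 0.999 * template.r0  # keep the waist the minimum
        rot_l = tuple(rng.normal(0.0, spec.condyle_rot_sd, 3))
        rot_r = tuple(rng.normal(0.0, spec.condyle_rot_sd, 3))
        tr_l = tuple(rng.normal(0.0, spec.condyle_trans_sd, 3))
        tr_r = tuple(rng.normal(0.0, spec.condyle_trans_sd, 3))
        truth = PhantomTruth(
            condyle_left_rot=rot_l,
            condyle_left_trans=tr_l,
            condyle_right_rot=rot_r,
            condyle_right_trans=tr_r,
            symphysis_shift=(float(s_dx[i]), float(s_dz[i])),
            pre_profile=template,
            post_profile=replace(template, waist_min=waist_post),
            noise_sd=0.0,
            seed=int(rng.integers(2**31)),
            segments=spec.segments,
            ring_spacing=spec.ring_spacing,
            label=f"subject_{i:03d}",
        )
        truths.append(truth)
        rows.append(
            {
                "subject": truth.label,
                "s_dx_true": s_dx[i],
                "s_dz_true": s_dz[i],
                "hypo_mincsa_pct_true": (waist_post / template.waist_min) ** 2 * 100.0,
                "L_rot_x": rot_l[0],
                "L_rot_y": rot_l[1],
                "L_rot_z": rot_l[2],
                "R_rot_x": rot_r[0],
                "R_rot_y": rot_r[1],
                "R_rot_z": rot_r[2],
            }
        )
    return truths, pd.DataFrame(rows)
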