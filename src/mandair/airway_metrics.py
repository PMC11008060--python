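"""Upper-airway segmentation, volumetry and cross-sectional area profiles.

The airway lumen is divided into naso-, oro- and hypopharynx by four
reference planes (top of nasopharynx, naso/oro boundary, the epiglottis
E-plane separating oro- from hypopharynx, and the hypopharynx floor), ordered
cranio-caudally with cranially oriented normals.  Segment volumes, their
percentage change post/pre, and 1 mm cross-sectional area (CSA) profiles
measured on planes parallel to the E-plane are computed, with the minimum CSA
(minCSA) of the oro- and hypopharynx localised on the profile.

Sampling conventions (documented and auditable):

* profile planes are parallel to the E-plane, not orthogonal to an airway
  centreline;
* offsets are signed — positive cranial (oropharynx), negative caudal
  (hypopharynx);
* offset 0 (the E-plane itself) is book-kept with the hypopharynx but also
  enters the oropharyngeal minimum, and both minima are reported with their
  offsets;
* sampled offsets are the multiples of the spacing strictly inside the
  segment bounds (half-open at the far plane), so boundary planes between
  segments are never counted twice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .errors import EmptyContourError, EmptyGeometryError, ValidationError
from .mesh_core import (
    Plane,
    SurfaceMesh,
    clip_between_planes,
    contour_area,
    mesh_volume,
    section_with_plane,
)

log = logging.getLogger(__name__)

SEGMENT_NAMES = ("naso", "oro", "hypo")


@dataclass(frozen=True)
class AirwayPlanes:
    """The four cranio-caudally ordered reference planes.

    Invariants: all normals oriented cranially (positive component on the
    common axis) and signed offsets strictly decreasing top → bottom.
    """

    top: Plane
    naso_oro: Plane
    e_plane: Plane
    bottom: Plane

    def __post_init__(self):
        axis = self.axis
        offs = self.offsets
        if not all(p.normal @ axis > 0.0 for p in self.planes):
            raise ValidationError("airway plane normals must be oriented cranially")
        if not (offs[0] > offs[1] > offs[2] > offs[3]):
            raise ValidationError(
                f"airway planes out of cranio-caudal order (offsets {offs})"
            )

    @property
    def planes(self) -> tuple[Plane, Plane, Plane, Plane]:
        return (self.top, self.naso_oro, self.e_plane, self.bottom)

    @property
    def axis(self) -> np.ndarray:
        """Common cranial axis (mean of the plane normals, normalised)."""
        n = np.mean([p.normal for p in self.planes], axis=0)
        return n / np.linalg.norm(n)

    @property
    def offsets(self) -> np.ndarray:
        """Signed offsets of the plane points along the common axis."""
        axis = np.mean([p.normal for p in self.planes], axis=0)
        axis = axis / np.linalg.norm(axis)
        return np.array([p.point @ axis for p in self.planes])

    @classmethod
    def from_z_offsets(
        cls, top: float, naso_oro: float, e_plane: float, bottom: float
    ) -> "AirwayPlanes":
        """Planes orthogonal to the frame Z axis at the given Z offsets."""
        z = np.array([0.0, 0.0, 1.0])
        return cls(
            top=Plane([0, 0, top], z),
            naso_oro=Plane([0, 0, naso_oro], z),
            e_plane=Plane([0, 0, e_plane], z),
            bottom=Plane([0, 0, bottom], z),
        )

    def to_dict(self) -> dict:
        return {
            name: {"point": p.point.tolist(), "normal": p.normal.tolist()}
            for name, p in zip(("top", "naso_oro", "e_plane", "bottom"), self.planes)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AirwayPlanes":
        return cls(
            **{
                name: Plane(d[name]["point"], d[name]["normal"])
                for name in ("top", "naso_oro", "e_plane", "bottom")
            }
        )


@dataclass(frozen=True)
class AirwaySegmentVolumes:
    naso: float
    oro: float
    hypo: float
    total: float
    timepoint: Literal["pre", "post"]

    def __post_init__(self):
        if min(self.naso, self.oro, self.hypo) < 0:
            raise ValidationError("segment volumes must be non-negative")
        if not math.isclose(self.total, self.naso + self.oro + self.hypo, rel_tol=1e-6, abs_tol=1e-9):
            raise ValidationError("total volume must equal the sum of segments")

    def as_dict(self) -> dict:
        return {
            "naso": self.naso,
            "oro": self.oro,
            "hypo": self.hypo,
            "total": self.total,
        }


@dataclass
class AirwayProfile:
    """CSA samples at fixed spacing from the E-plane, plus segment minima.

    ``offsets`` are signed mm from the E-plane (descending, cranial first);
    ``areas`` the matching CSAs in mm^2; ``segment`` labels each sample
    "oro" or "hypo" (offset 0 belongs to "hypo").
    """

    offsets: np.ndarray
    areas: np.ndarray
    segment: np.ndarray
    spacing: float
    min_csa_oro: float | None
    min_csa_oro_offset: float | None
    min_csa_hypo: float | None
    min_csa_hypo_offset: float | None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, float)
        self.areas = np.asarray(self.areas, float)
        if (self.areas < 0).any():
            raise ValidationError("profile areas must be non-negative")
        if len(self.offsets) > 1:
            steps = -np.diff(self.offsets)
            if not np.allclose(steps, self.spacing, rtol=0, atol=1e-9):
                raise ValidationError("profile offsets must be evenly spaced")


@dataclass(frozen=True)
class AirwayChange:
    """Percentage change (post/pre x 100) per quantity; 100 = no change."""

    volume_pct: dict
    min_csa_pct: dict

    def as_dict(self) -> dict:
        out = {f"vol_{k}_pct": v for k, v in self.volume_pct.items()}
        out.update({f"mincsa_{k}_pct": v for k, v in self.min_csa_pct.items()})
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _segment_bounds(planes: AirwayPlanes) -> dict:
    return {
        "naso": (planes.naso_oro, planes.top),
        "oro": (planes.e_plane, planes.naso_oro),
        "hypo": (planes.bottom, planes.e_plane),
    }


def segment_airway(lumen: SurfaceMesh, planes: AirwayPlanes) -> dict:
    """Clip the lumen into the three pharyngeal segments (each watertight).

    Returns ``{"naso": mesh, "oro": mesh, "hypo": mesh}``.
    """
    out = {}
    for name, (caudal, cranial) in _segment_bounds(planes).items():
        try:
            out[name] = clip_between_planes(lumen, caudal, cranial.flipped())
        except EmptyGeometryError as exc:
            raise EmptyGeometryError(
                f"lumen does not reach the {name}pharynx segment: {exc}"
            ) from exc
        out[name].name = f"{lumen.name}_{name}"
    return out


def airway_volumes(
    lumen: SurfaceMesh, planes: AirwayPlanes, timepoint: Literal["pre", "post"]
) -> AirwaySegmentVolumes:
    """Segment volumes via the capped clipped sub-meshes."""
    vols = {}
    for name, (caudal, cranial) in _segment_bounds(planes).items():
        span = cranial.point @ planes.axis - caudal.point @ planes.axis
        if span <= 1e-9:
            log.warning("zero-length %spharynx segment; volume set to 0", name)
            vols[name] = 0.0
            continue
        seg = clip_between_planes(lumen, caudal, cranial.flipped())
        vols[name] = mesh_volume(seg)
    return AirwaySegmentVolumes(
        naso=vols["naso"],
        oro=vols["oro"],
        hypo=vols["hypo"],
        total=vols["naso"] + vols["oro"] + vols["hypo"],
        timepoint=timepoint,
    )


def _profile_offsets(planes: AirwayPlanes, spacing: float, segments: Iterable[str]):
    """(offset, segment-label) pairs, cranial first.

    Oropharynx: positive multiples of ``spacing`` strictly below the naso/oro
    plane.  Hypopharynx: offset 0 and negative multiples strictly above the
    bottom plane (half-open at the far planes).
    """
    offs = planes.offsets
    e = offs[2]
    pairs = []
    if "oro" in segments:
        upper = offs[1] - e
        k = 1
        while k * spacing < upper - 1e-9:
            pairs.append((k * spacing, "oro"))
            k += 1
        pairs.reverse()
    if "hypo" in segments:
        lower = offs[3] - e
        k = 0
        while -k * spacing > lower + 1e-9:
            pairs.append((-k * spacing, "hypo"))
            k += 1
    return pairs


def csa_profile(
    lumen: SurfaceMesh,
    planes: AirwayPlanes,
    spacing: float = 1.0,
    area_mode: Literal["sum", "largest"] = "sum",
    segments: Iterable[str] = ("oro", "hypo"),
) -> AirwayProfile:
    """Cross-sectional area profile on planes parallel to the E-plane.

    An empty section at an interior offset is recorded as area 0 with a
    discontinuity warning (possible collapsed lumen).
    """
    pairs = _profile_offsets(planes, spacing, segments)
    if not pairs:
        raise ValidationError("no profile offsets inside the segment bounds")
    warnings: list[str] = []
    areas = np.empty(len(pairs))
    for i, (off, _seg) in enumerate(pairs):
        plane = planes.e_plane.shifted(off)
        try:
            contour = section_with_plane(lumen, plane)
            areas[i] = contour_area(contour, mode=area_mode)
        except EmptyContourError:
            msg = f"empty section at offset {off:+.1f} mm (collapsed lumen?)"
            log.warning("%s: %s", lumen.name, msg)
            warnings.append(msg)
            areas[i] = 0.0
    offsets = np.array([p[0] for p in pairs])
    seg_labels = np.array([p[1] for p in pairs])

    def seg_min(label: str):
        mask = seg_labels == label
        if label == "oro":
            # E-plane (offset 0) also competes for the oropharyngeal minimum
            mask = mask | (offsets == 0.0)
        if not mask.any():
            return None, None
        idx = np.flatnonzero(mask)[np.argmin(areas[mask])]
        return float(areas[idx]), float(offsets[idx])

    min_oro, off_oro = seg_min("oro") if "oro" in segments else (None, None)
    min_hypo, off_hypo = seg_min("hypo") if "hypo" in segments else (None, None)
    return AirwayProfile(
        offsets=offsets,
        areas=areas,
        segment=seg_labels,
        spacing=spacing,
        min_csa_oro=min_oro,
        min_csa_oro_offset=off_oro,
        min_csa_hypo=min_hypo,
        min_csa_hypo_offset=off_hypo,
        warnings=warnings,
    )


def airway_change(
    pre_volumes: AirwaySegmentVolumes,
    post_volumes: AirwaySegmentVolumes,
    pre_profile: AirwayProfile | None = None,
    post_profile: AirwayProfile | None = None,
) -> AirwayChange:
    """Percentage change post/pre for segment volumes and minCSAs."""

    def pct(post: float, pre: float, what: str) -> float:
        if pre <= 0:
            raise ValidationError(f"undefined percentage: pre-operative {what} is zero")
        return 100.0 * post / pre

    vol = {
        k: pct(post_volumes.as_dict()[k], pre_volumes.as_dict()[k], f"{k} volume")
        for k in ("naso", "oro", "hypo", "total")
    }
    mincsa = {}
    if pre_profile is not None and post_profile is not None:
        for key in ("oro", "hypo"):
            pre_v = getattr(pre_profile, f"min_csa_{key}")
            post_v = getattr(post_profile, f"min_csa_{key}")
            if pre_v is not None and post_v is not None:
                mincsa[key] = pct(post_v, pre_v, f"{key} minCSA")
    return AirwayChange(volume_pct=vol, min_csa_pct=mincsa)


def profile_dataframe(profile: AirwayProfile, patient: str, timepoint: str):
    """Tidy rows (patient, timepoint, segment, offset_mm, area_mm2)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient": patient,
            "timepoint": timepoint,
            "segment": profile.segment,
            "offset_mm": profile.offsets,
            "area_mm2": profile.areas,
        }
    )


def plot_profiles(pre: AirwayProfile, post: AirwayProfile, path) -> None:
    """Overlay pre/post CSA profiles (area vs offset from the E-plane)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pre.offsets, pre.areas, label="pre", marker=".")
    ax.plot(post.offsets, post.areas, label="post", marker=".")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("offset from E-plane [mm] (cranial positive)")
    ax.set_ylabel("cross-sectional area [mm²]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
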