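"""Surface-mesh primitives: STL I/O, volumes, plane sections and slab clipping.

All geometry is in millimetres.  Meshes are triangulated surfaces; volume
computations require watertight, consistently oriented input (the signed
tetrahedron sum is only meaningful on a closed surface).  STL stores float32
coordinates; everything in memory is float64 so that summation error stays far
below the measurement scale.

The plane-section machinery chains the raw triangle/plane crossing segments
into closed loops with an endpoint-matching tolerance of ``CHAIN_TOL`` (1e-6
mm, well below CT voxel scale).  Nested loops are combined with even-odd
(alternating-sign) semantics, so a lumen with an island does not overcount.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Literal

import numpy as np
import trimesh
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    EmptyContourError,
    EmptyGeometryError,
    GeometryError,
    NonWatertightError,
    StlFormatError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: endpoint-matching tolerance for chaining section segments into loops [mm]
CHAIN_TOL = 1e-6
#: faces with area below this are dropped at load [mm^2]
DEGENERATE_AREA = 1e-12
#: vertex-merge tolerance at load [mm]
MERGE_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"mesh {self.name!r}: non-finite vertex coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError(f"mesh {self.name!r}: face index out of range")

    # -- conversions -------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        """The trimesh view of this mesh (cached; do not mutate)."""
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, int), name)

    # -- basic properties --------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def boundary_edge_count(self) -> int:
        tm = self.to_trimesh()
        edges = tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts == 1).sum())

    def surface_centroid(self) -> np.ndarray:
        """Area-weighted centroid of the surface (the rigid-body reference
        point used for region displacement reporting)."""
        return np.asarray(self.to_trimesh().centroid, float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), self.name)

    def concatenated(self, *others: "SurfaceMesh", name: str = "") -> "SurfaceMesh":
        verts = [self.vertices] + [o.vertices for o in others]
        faces = [self.faces]
        offset = len(self.vertices)
        for o in others:
            faces.append(o.faces + offset)
            offset += len(o.vertices)
        return SurfaceMesh(np.vstack(verts), np.vstack(faces), name or self.name)


@dataclass(frozen=True)
class Plane:
    """An oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValidationError("plane normal must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    @property
    def offset(self) -> float:
        """Signed distance of the plane from the origin along its normal."""
        return float(self.point @ self.normal)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """A deterministic orthonormal in-plane basis (e1, e2) with
        e1 x e2 = normal."""
        n = self.normal
        helper = np.zeros(3)
        helper[np.argmin(np.abs(n))] = 1.0
        e1 = np.cross(n, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    def shifted(self, distance: float) -> "Plane":
        """Parallel plane displaced ``distance`` mm along the normal."""
        return Plane(self.point + distance * self.normal, self.normal)

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass
class SectionContour:
    """Closed intersection loops of a mesh with a plane.

    ``loops`` are (k, 3) arrays of ordered points lying on ``plane`` (implicit
    closure: the last point connects back to the first), ordered by descending
    enclosed area.
    """

    loops: list[np.ndarray]
    plane: Plane

    def __post_init__(self):
        for lp in self.loops:
            d = np.abs(self.plane.signed_distance(lp))
            if d.max() > 1e-5:
                raise ValidationError(
                    f"contour loop off-plane by {d.max():.2e} mm"
                )

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def loops_2d(self) -> list[np.ndarray]:
        """Loops projected into the plane's (e1, e2) coordinates."""
        e1, e2 = self.plane.basis()
        origin = self.plane.point
        return [
            np.column_stack(((lp - origin) @ e1, (lp - origin) @ e2))
            for lp in self.loops
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "plane": {
                    "point": self.plane.point.tolist(),
                    "normal": self.plane.normal.tolist(),
                },
                "loops": [lp.tolist() for lp in self.loops],
            }
        )


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned box or sphere region, in frame coordinates.

    ``kind`` is "box" (``bounds`` = (min_xyz, max_xyz)) or "sphere"
    (``center``, ``radius``).
    """

    kind: Literal["box", "sphere"]
    bounds: tuple | None = None
    center: tuple | None = None
    radius: float | None = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "box":
            lo, hi = (np.asarray(b, float) for b in self.bounds)
            return np.all((pts >= lo) & (pts <= hi), axis=1)
        if self.kind == "sphere":
            c = np.asarray(self.center, float)
            return np.linalg.norm(pts - c, axis=1) <= float(self.radius)
        raise ValidationError(f"unknown region kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        kind = d["kind"]
        if kind == "box":
            return cls(kind="box", bounds=(tuple(d["min"]), tuple(d["max"])))
        if kind == "sphere":
            return cls(kind="sphere", center=tuple(d["center"]), radius=float(d["radius"]))
        raise ValidationError(f"unknown region kind {kind!r}")

    def to_dict(self) -> dict:
        if self.kind == "box":
            return {"kind": "box", "min": list(self.bounds[0]), "max": list(self.bounds[1])}
        return {"kind": "sphere", "center": list(self.center), "radius": self.radius}


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def _check_binary_stl_size(path: FilePath) -> None:
    """For binary STL, verify the advertised facet count matches the file
    length, so truncation is reported with the offending byte offset."""
    size = path.stat().st_size
    if size < 15:
        raise StlFormatError(f"{path}: file too short ({size} bytes) to be an STL")
    with open(path, "rb") as fh:
        head = fh.read(5)
        if head.lower() == b"solid":
            return  # ASCII candidates are validated by the parser
        fh.seek(80)
        count_bytes = fh.read(4)
        if len(count_bytes) < 4:
            raise StlFormatError(f"{path}: truncated binary STL header at byte 80")
        (n_facets,) = struct.unpack("<I", count_bytes)
        expected = 84 + 50 * n_facets
        if size < expected:
            raise StlFormatError(
                f"{path}: truncated binary STL — header promises {n_facets} facets "
                f"({expected} bytes) but the file ends at byte {size}"
            )


def read_stl(path, name: str | None = None) -> SurfaceMesh:
    """Read and validate an STL file (binary or ASCII).

    Duplicate vertices within 1e-6 mm are merged, duplicate and degenerate
    (area < 1e-12 mm^2) faces are dropped; counts are logged.
    """
    path = FilePath(path)
    if not path.exists():
        raise StlFormatError(f"{path}: file does not exist")
    _check_binary_stl_size(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise StlFormatError(f"{path}: unreadable STL ({exc})") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyGeometryError(f"{path}: STL contains no geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise EmptyGeometryError(f"{path}: STL contains no geometry")
    mesh = clean_mesh(
        SurfaceMesh.from_trimesh(tm, name or path.stem), source=str(path)
    )
    return mesh


def clean_mesh(mesh: SurfaceMesh, source: str = "") -> SurfaceMesh:
    """Merge near-duplicate vertices, drop duplicate and degenerate faces."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    n_vert0, n_face0 = len(tm.vertices), len(tm.faces)
    tm.merge_vertices(digits_vertex=int(round(-np.log10(MERGE_TOL))))
    # drop faces that repeat an identical vertex triple (either winding)
    sorted_faces = np.sort(tm.faces, axis=1)
    _, first_idx = np.unique(sorted_faces, axis=0, return_index=True)
    keep = np.zeros(len(tm.faces), bool)
    keep[first_idx] = True
    n_dupl = int((~keep).sum())
    tm.update_faces(keep)
    # drop degenerate faces and self-referencing triples
    tri = tm.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    distinct = (
        (tm.faces[:, 0] != tm.faces[:, 1])
        & (tm.faces[:, 1] != tm.faces[:, 2])
        & (tm.faces[:, 0] != tm.faces[:, 2])
    )
    good = (areas >= DEGENERATE_AREA) & distinct
    n_degen = int((~good).sum())
    tm.update_faces(good)
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise EmptyGeometryError(f"{source or mesh.name}: no faces left after cleaning")
    merged = n_vert0 - len(tm.vertices)
    if merged or n_dupl or n_degen:
        log.warning(
            "%s: merged %d duplicate vertices, dropped %d duplicate and %d "
            "degenerate faces",
            source or mesh.name or "mesh",
            merged,
            n_dupl,
            n_degen,
        )
    return SurfaceMesh.from_trimesh(tm, mesh.name)


def write_stl(mesh: SurfaceMesh, path, binary: bool = True) -> None:
    """Write a mesh as STL (float32 on disk, as the format requires)."""
    path = FilePath(path)
    tm = mesh.to_trimesh()
    data = trimesh.exchange.stl.export_stl(tm) if binary else trimesh.exchange.stl.export_stl_ascii(tm).encode()
    path.write_bytes(data)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mm^3 by signed-tetrahedron summation.

    Requires a watertight, consistently oriented mesh; an inside-out (negative
    signed volume) mesh is reported positive with a warning.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise NonWatertightError(
            f"mesh {mesh.name!r} is not watertight: "
            f"{mesh.boundary_edge_count()} boundary edges"
        )
    vol = float(tm.volume)
    if vol < 0:
        log.warning("mesh %r has inward orientation; reporting |volume|", mesh.name)
        vol = -vol
    return vol


@dataclass(frozen=True)
class VolumeQCReport:
    passed: bool
    volume_pre: float
    volume_post: float
    ratio: float
    tolerance: float


def volume_qc(
    pre: SurfaceMesh, post: SurfaceMesh, tolerance: float = 0.02
) -> VolumeQCReport:
    """Segmentation quality check: compare total volumes of anatomically
    stable reference geometry between time points.

    Fails when ``|post/pre - 1| > tolerance``.  Which structures to compare
    (whole bone STL vs a stable subregion) is the caller's choice; the
    pipeline default is the whole bone mesh.
    """
    v_pre = mesh_volume(pre)
    v_post = mesh_volume(post)
    ratio = v_post / v_pre
    return VolumeQCReport(
        passed=bool(abs(ratio - 1.0) <= tolerance),
        volume_pre=v_pre,
        volume_post=v_post,
        ratio=ratio,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# planar sections
# ---------------------------------------------------------------------------


def _chain_segments(segments: np.ndarray, tol: float) -> list[np.ndarray]:
    """Chain (n, 2, 3) crossing segments into closed loops.

    Endpoints are matched by rounding to a ``tol`` grid.  Raises
    :class:`GeometryError` on open chains (cut through a boundary).
    """
    # quantise endpoints onto the tolerance grid and identify shared nodes
    keys = np.round(segments.reshape(-1, 3) / tol).astype(np.int64)
    _, node_of = np.unique(keys, axis=0, return_inverse=True)
    nodes = node_of.reshape(-1, 2)
    # drop zero-length segments
    mask = nodes[:, 0] != nodes[:, 1]
    segments, nodes = segments[mask], nodes[mask]
    if len(segments) == 0:
        raise EmptyContourError("no intersection segments after filtering")
    # dedupe identical segments (shared coplanar edges produce copies)
    sorted_nodes = np.sort(nodes, axis=1)
    _, first = np.unique(sorted_nodes, axis=0, return_index=True)
    keep = np.zeros(len(segments), bool)
    keep[first] = True
    segments, nodes = segments[keep], nodes[keep]

    adjacency: dict[int, list[tuple[int, int]]] = {}
    for i, (a, b) in enumerate(nodes):
        adjacency.setdefault(int(a), []).append((i, 0))
        adjacency.setdefault(int(b), []).append((i, 1))

    used = np.zeros(len(segments), bool)
    loops: list[np.ndarray] = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        pts = [segments[start, 0], segments[start, 1]]
        start_node = int(nodes[start, 0])
        current = int(nodes[start, 1])
        while current != start_node:
            candidates = [
                (i, end) for i, end in adjacency.get(current, []) if not used[i]
            ]
            if not candidates:
                raise GeometryError(
                    "open intersection chain (non-watertight cut); endpoints "
                    f"{np.asarray(pts[0])} and {np.asarray(pts[-1])}"
                )
            i, end = candidates[0]
            used[i] = True
            current = int(nodes[i, 1 - end])
            if current != start_node:
                pts.append(segments[i, 1 - end])
        loops.append(np.asarray(pts))
    return loops


def _shoelace(loop2d: np.ndarray) -> float:
    """Signed area of a closed 2D polygon (implicit closure)."""
    x, y = loop2d[:, 0], loop2d[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _loop_signs(loops2d: list[np.ndarray]) -> np.ndarray:
    """Even-odd signs: +1 for loops at even containment depth, -1 odd."""
    polys = [ShapelyPolygon(lp) for lp in loops2d]
    signs = np.ones(len(loops2d))
    for i, lp in enumerate(loops2d):
        # a vertex of the loop itself: inside exactly the loops enclosing it
        pt = ShapelyPoint(lp[0])
        depth = sum(
            1 for j, other in enumerate(polys) if j != i and other.contains(pt)
        )
        signs[i] = 1.0 if depth % 2 == 0 else -1.0
    return signs


def section_with_plane(mesh: SurfaceMesh, plane: Plane) -> SectionContour:
    """Intersect a mesh with a plane, returning closed loops ordered by
    descending enclosed area."""
    tm = mesh.to_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=plane.normal, plane_origin=plane.point
    )
    if len(segments) == 0:
        raise EmptyContourError(
            f"plane (offset {plane.offset:.3f} mm) does not intersect mesh "
            f"{mesh.name!r}"
        )
    loops = _chain_segments(np.asarray(segments, float), CHAIN_TOL)
    # snap exactly onto the plane (kills float noise from the crossing solve)
    snapped = []
    for lp in loops:
        d = plane.signed_distance(lp)
        snapped.append(lp - np.outer(d, plane.normal))
    contour = SectionContour(loops=snapped, plane=plane)
    areas = [abs(_shoelace(lp)) for lp in contour.loops_2d()]
    order = np.argsort(areas)[::-1]
    contour.loops = [contour.loops[i] for i in order]
    return contour


def contour_area(
    contour: SectionContour, mode: Literal["sum", "largest"] = "sum"
) -> float:
    """Enclosed planar area in mm^2.

    ``sum`` combines all loops with even-odd hole semantics (nested loops
    subtract); ``largest`` returns the single loop of maximal area.
    """
    if contour.n_loops < 1:
        raise GeometryError("contour has no loops")
    loops2d = contour.loops_2d()
    for lp in loops2d:
        if len(lp) >= 3 and not ShapelyPolygon(lp).is_valid:
            raise GeometryError("self-intersecting section loop")
    areas = np.array([abs(_shoelace(lp)) for lp in loops2d])
    if mode == "largest":
        return float(areas.max())
    if mode == "sum":
        signs = _loop_signs(loops2d)
        return float(np.sum(signs * areas))
    raise ValidationError(f"unknown area mode {mode!r}")


def contour_centroid(contour: SectionContour) -> np.ndarray:
    """Area-weighted centroid of the enclosed planar region, in 3D.

    This is the centroid of the region (holes subtract with even-odd
    semantics), not the vertex mean, so it is robust to non-uniform
    tessellation.  The result lies on the contour's plane.
    """
    if contour.n_loops < 1:
        raise GeometryError("contour has no loops")
    loops2d = contour.loops_2d()
    signs = _loop_signs(loops2d)
    total = 0.0
    accum = np.zeros(2)
    for lp, sign in zip(loops2d, signs):
        a_signed = _shoelace(lp)
        a = abs(a_signed)
        if a < 1e-14:
            continue
        x, y = lp[:, 0], lp[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        cx = np.sum((x + xn) * cross) / (6.0 * a_signed)
        cy = np.sum((y + yn) * cross) / (6.0 * a_signed)
        accum += sign * a * np.array([cx, cy])
        total += sign * a
    if abs(total) < 1e-12:
        raise GeometryError("contour encloses zero area; centroid undefined")
    c2d = accum / total
    e1, e2 = contour.plane.basis()
    return contour.plane.point + c2d[0] * e1 + c2d[1] * e2


# ---------------------------------------------------------------------------
# slab clipping
# ---------------------------------------------------------------------------


def _cap_boundary_loops(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close every open boundary loop with a centroid fan.

    The fan preserves orientation (each boundary edge is traversed once in
    each direction) and yields exact enclosed volume for planar boundaries
    even when the loop is non-convex, because the fan triangle areas are
    signed.
    """
    tm = tm.copy()
    tm.merge_vertices()  # the cut introduces per-triangle duplicate vertices
    distinct = (
        (tm.faces[:, 0] != tm.faces[:, 1])
        & (tm.faces[:, 1] != tm.faces[:, 2])
        & (tm.faces[:, 0] != tm.faces[:, 2])
    )
    tm.update_faces(distinct)
    edges = tm.edges  # directed, per face
    edges_sorted = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        edges_sorted, axis=0, return_inverse=True, return_counts=True
    )
    boundary = counts[inverse] == 1
    bedges = edges[boundary]
    if len(bedges) == 0:
        return tm
    nxt = {int(a): int(b) for a, b in bedges}
    if len(nxt) != len(bedges):
        raise GeometryError("non-manifold boundary; cannot cap")
    vertices = [np.asarray(tm.vertices, float)]
    faces = [np.asarray(tm.faces, int)]
    n_vert = len(tm.vertices)
    visited: set[int] = set()
    for start in list(nxt):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in visited or cur not in nxt:
                raise GeometryError("open boundary chain; cannot cap")
            loop.append(cur)
            visited.add(cur)
            cur = nxt[cur]
        loop_pts = np.asarray(tm.vertices)[loop]
        centroid = loop_pts.mean(axis=0)
        c_idx = n_vert
        vertices.append(centroid[None, :])
        n_vert += 1
        loop_next = loop[1:] + loop[:1]
        cap = np.column_stack(
            [np.full(len(loop), c_idx), loop_next, loop]
        )
        faces.append(cap)
    return trimesh.Trimesh(
        vertices=np.vstack(vertices), faces=np.vstack(faces), process=False
    )


def clip_between_planes(
    mesh: SurfaceMesh, lower: Plane, upper: Plane
) -> SurfaceMesh:
    """Watertight sub-mesh between two planes whose normals point into the
    kept slab, with the cut sections capped so volumes remain valid."""
    if (upper.signed_distance(lower.point) < 0).all() and (
        lower.signed_distance(upper.point) < 0
    ).all():
        raise EmptyGeometryError("slab between planes is empty")
    tm = mesh.to_trimesh()
    for plane in (lower, upper):
        tm = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=plane.normal, plane_origin=plane.point, cap=False
        )
        if tm is None or len(tm.faces) == 0:
            raise EmptyGeometryError(
                f"clip of {mesh.name!r} is empty at plane offset "
                f"{plane.offset:.3f} mm"
            )
        tm = _cap_boundary_loops(tm)
    tm.merge_vertices()
    out = SurfaceMesh.from_trimesh(tm, mesh.name)
    if not out.is_watertight():
        raise GeometryError(
            f"capping failed for {mesh.name!r}: "
            f"{out.boundary_edge_count()} boundary edges remain"
        )
    return out


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def crop_faces(mesh: SurfaceMesh, spec: RegionSpec, name: str = "") -> SurfaceMesh:
    """Sub-mesh of faces whose centroids fall inside ``spec``."""
    tm = mesh.to_trimesh()
    centroids = tm.triangles.mean(axis=1)
    mask = spec.contains(centroids)
    if not mask.any():
        raise EmptyGeometryError(
            f"region crop of {mesh.name!r} is empty ({spec.kind})"
        )
    faces = mesh.faces[mask]
    used = np.unique(faces)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], name or mesh.name)
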