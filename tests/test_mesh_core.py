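"""Geometric primitives: STL I/O, volumes, sections, clipping."""

import struct

import numpy as np
import pytest
import trimesh

from mandair import phantom as ph
from mandair.errors import (
    EmptyContourError,
    EmptyGeometryError,
    GeometryError,
    NonWatertightError,
    StlFormatError,
)
from mandair.mesh_core import (
    Plane,
    SectionContour,
    SurfaceMesh,
    clip_between_planes,
    contour_area,
    contour_centroid,
    mesh_volume,
    read_stl,
    section_with_plane,
    volume_qc,
    write_stl,
)

from conftest import random_rigid

SPHERE_VOL_10 = 4.0 / 3.0 * np.pi * 1000.0  # 4188.79 mm^3


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


class TestReadStl:
    def test_ascii_cube_merges_duplicate_vertices(self, ascii_cube_stl):
        mesh = read_stl(ascii_cube_stl)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12

    def test_duplicate_facet_dropped_with_warning(self, tmp_path, caplog):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        header = b"\0" * 80 + struct.pack("<I", 2)
        facet = struct.pack("<3f", 0, 0, 1) + tri.astype("<f4").tobytes() + b"\0\0"
        path = tmp_path / "dup.stl"
        path.write_bytes(header + facet + facet)
        with caplog.at_level("WARNING"):
            mesh = read_stl(path)
        assert mesh.n_faces == 1
        assert "duplicate" in caplog.text

    def test_truncated_binary_is_format_error(self, tmp_path):
        header = b"\0" * 80 + struct.pack("<I", 100)  # promises 100 facets
        path = tmp_path / "trunc.stl"
        path.write_bytes(header + b"\0" * 30)
        with pytest.raises(StlFormatError, match="byte"):
            read_stl(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StlFormatError):
            read_stl(tmp_path / "nope.stl")

    def test_roundtrip_preserves_float32_coordinates(self, tmp_path, icosphere10):
        path = tmp_path / "rt.stl"
        write_stl(icosphere10, path)
        back = read_stl(path)
        # STL stores float32; coordinates survive to that precision
        assert back.n_vertices == icosphere10.n_vertices
        orig = np.sort(icosphere10.vertices.astype(np.float32).ravel())
        new = np.sort(back.vertices.astype(np.float32).ravel())
        assert np.array_equal(orig, new)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


class TestMeshVolume:
    def test_unit_cube(self, ascii_cube_stl):
        assert mesh_volume(read_stl(ascii_cube_stl)) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere_within_half_percent(self, icosphere10):
        assert mesh_volume(icosphere10) == pytest.approx(SPHERE_VOL_10, rel=5e-3)

    def test_rigid_invariance(self, icosphere10, rng):
        t = random_rigid(rng)
        moved = t.apply_mesh(icosphere10)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(icosphere10), rel=1e-9)

    def test_non_watertight_error_reports_boundary_edges(self, icosphere10):
        open_mesh = SurfaceMesh(icosphere10.vertices, icosphere10.faces[:-10], "open")
        with pytest.raises(NonWatertightError, match="boundary edges"):
            mesh_volume(open_mesh)


class TestVolumeQC:
    def test_identical_meshes_pass(self, icosphere10):
        report = volume_qc(icosphere10, icosphere10, tolerance=0.02)
        assert report.passed and report.ratio == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "tolerance,expected_pass", [(0.02, False), (0.07, True)]
    )
    def test_radius_mismatch_against_analytic_ratio(
        self, icosphere10, tolerance, expected_pass
    ):
        # r=10 vs r=10.2: volume ratio (10.2/10)^3 ~ 1.0612
        bigger = SurfaceMesh(icosphere10.vertices * 1.02, icosphere10.faces, "big")
        report = volume_qc(icosphere10, bigger, tolerance=tolerance)
        assert report.passed is expected_pass
        assert report.ratio == pytest.approx(1.02**3, rel=1e-9)


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------


class TestSectionWithPlane:
    def test_cylinder_cross_section_area(self, cylinder_r5, z_plane):
        contour = section_with_plane(cylinder_r5, z_plane)
        assert contour.n_loops == 1
        assert contour_area(contour) == pytest.approx(25 * np.pi, rel=5e-3)

    def test_torus_cut_through_hole_axis_gives_two_loops(self):
        tm = trimesh.creation.torus(major_radius=10.0, minor_radius=3.0)
        mesh = SurfaceMesh.from_trimesh(tm, "torus")
        contour = section_with_plane(mesh, Plane([0, 0, 0], [0, 1, 0]))
        assert contour.n_loops == 2

    def test_missing_plane_is_empty_contour_error(self, cylinder_r5):
        with pytest.raises(EmptyContourError):
            section_with_plane(cylinder_r5, Plane([0, 0, 100.0], [0, 0, 1]))

    def test_area_invariant_under_common_rigid_motion(self, cylinder_r5, z_plane, rng):
        a0 = contour_area(section_with_plane(cylinder_r5, z_plane))
        t = random_rigid(rng)
        moved = t.apply_mesh(cylinder_r5)
        moved_plane = Plane(t.apply(z_plane.point), t.rotation @ z_plane.normal)
        a1 = contour_area(section_with_plane(moved, moved_plane))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_section_area_continuous_along_tube(self):
        """Adjacent 0.1 mm offsets on a smooth waisted tube differ boundedly
        (no spikes from loop-chaining bugs)."""
        profile = ph.RadiusProfile(r0=6.0, waist_min=3.0, waist_center=0.0, waist_width=5.0)
        z = np.linspace(-15.25, 15.25, 62)
        tube = ph.tube_mesh(z, profile(z), segments=96)
        areas = []
        for off in np.arange(-5.0, 5.0, 0.1):
            contour = section_with_plane(tube, Plane([0, 0, off], [0, 0, 1]))
            areas.append(contour_area(contour))
        steps = np.abs(np.diff(areas))
        # |dA/dz| <= 2 pi r |dr/dz| < 2 pi * 6 * 0.7 ~ 26 mm^2/mm -> 2.7 per 0.1mm
        assert steps.max() < 3.0


def _circle_loop(radius, n, center=(0.0, 0.0, 0.0), z=0.0, reverse=False):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t), np.full(n, z)]
    )
    return pts[::-1] if reverse else pts


class TestContourArea:
    def test_single_square(self, z_plane):
        square = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        contour = SectionContour([square], z_plane)
        assert contour_area(contour) == pytest.approx(4.0)

    def test_sum_and_largest_for_disjoint_squares(self, z_plane):
        s1 = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        s2 = np.array([[3, 0, 0], [5, 0, 0], [5, 2, 0], [3, 2, 0]], float)
        contour = SectionContour([s2, s1], z_plane)
        assert contour_area(contour, "sum") == pytest.approx(5.0)
        assert contour_area(contour, "largest") == pytest.approx(4.0)

    def test_annulus_hole_subtracts(self, z_plane):
        outer = _circle_loop(3.0, 256)
        inner = _circle_loop(1.0, 256)
        contour = SectionContour([outer, inner], z_plane)
        assert contour_area(contour, "sum") == pytest.approx(8 * np.pi, rel=5e-3)

    def test_self_intersecting_loop_is_geometry_error(self, z_plane):
        bowtie = np.array([[0, 0, 0], [2, 2, 0], [2, 0, 0], [0, 2, 0]], float)
        with pytest.raises(GeometryError, match="self-intersect"):
            contour_area(SectionContour([bowtie], z_plane))


class TestContourCentroid:
    def test_square_centroid(self):
        plane = Plane([0, 0, 2.0], [0, 0, 1])
        square = np.array(
            [[0.5, -0.5, 2], [1.5, -0.5, 2], [1.5, 0.5, 2], [0.5, 0.5, 2]], float
        )
        c = contour_centroid(SectionContour([square], plane))
        assert np.allclose(c, [1.0, 0.0, 2.0], atol=1e-12)

    def test_l_shape_against_rectangle_decomposition(self, z_plane):
        # L = [0,2]x[0,1] plus [0,1]x[1,3]: areas 2 and 2,
        # centroids (1, 0.5) and (0.5, 2) -> combined (0.75, 1.25)
        loop = np.array(
            [[0, 0, 0], [2, 0, 0], [2, 1, 0], [1, 1, 0], [1, 3, 0], [0, 3, 0]], float
        )
        c = contour_centroid(SectionContour([loop], z_plane))
        assert np.allclose(c[:2], [0.75, 1.25], atol=1e-12)

    def test_invariant_to_start_vertex_and_direction(self, z_plane, rng):
        loop = _circle_loop(4.0, 37, center=(2.0, -1.0, 0.0))
        c0 = contour_centroid(SectionContour([loop], z_plane))
        rolled = np.roll(loop, 11, axis=0)
        reversed_ = loop[::-1]
        for variant in (rolled, reversed_):
            c = contour_centroid(SectionContour([variant], z_plane))
            assert np.allclose(c, c0, atol=1e-9)

    def test_annulus_centroid_ignores_hole_position_weighting(self, z_plane):
        outer = _circle_loop(3.0, 256)
        inner = _circle_loop(1.0, 128, center=(1.0, 0.0, 0.0))
        c = contour_centroid(SectionContour([outer, inner], z_plane))
        # region centroid: (9pi*0 - pi*1)/(8pi) = -0.125 on x
        assert c[0] == pytest.approx(-0.125, abs=2e-3)


# ---------------------------------------------------------------------------
# clipping
# ---------------------------------------------------------------------------


class TestClipBetweenPlanes:
    def test_cylinder_middle_slab(self, cylinder_r5):
        clipped = clip_between_planes(
            cylinder_r5, Plane([0, 0, -5], [0, 0, 1]), Plane([0, 0, 5], [0, 0, -1])
        )
        assert clipped.is_watertight()
        assert mesh_volume(clipped) == pytest.approx(250 * np.pi, rel=5e-3)

    def test_planes_outside_mesh_preserve_volume(self, cylinder_r5):
        clipped = clip_between_planes(
            cylinder_r5, Plane([0, 0, -99], [0, 0, 1]), Plane([0, 0, 99], [0, 0, -1])
        )
        assert mesh_volume(clipped) == pytest.approx(mesh_volume(cylinder_r5), rel=1e-12)

    def test_hemisphere_volume(self, icosphere10):
        upper = clip_between_planes(
            icosphere10, Plane([0, 0, 0], [0, 0, 1]), Plane([0, 0, 20], [0, 0, -1])
        )
        assert mesh_volume(upper) == pytest.approx(2.0 / 3.0 * np.pi * 1000, rel=5e-3)

    def test_empty_slab_raises(self, cylinder_r5):
        with pytest.raises(EmptyGeometryError):
            clip_between_planes(
                cylinder_r5, Plane([0, 0, 5], [0, 0, 1]), Plane([0, 0, -5], [0, 0, -1])
            )

    @pytest.mark.parametrize("cut_z", [-3.7, 0.0, 4.2])
    def test_partition_conserves_volume(self, cylinder_r5, cut_z):
        total = mesh_volume(cylinder_r5)
        below = clip_between_planes(
            cylinder_r5, Plane([0, 0, -99], [0, 0, 1]), Plane([0, 0, cut_z], [0, 0, -1])
        )
        above = clip_between_planes(
            cylinder_r5, Plane([0, 0, cut_z], [0, 0, 1]), Plane([0, 0, 99], [0, 0, -1])
        )
        parts = mesh_volume(below) + mesh_volume(above)
        assert parts == pytest.approx(total, rel=1e-6)
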