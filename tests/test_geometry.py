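"""Mesh handling, conformal layering, projection and nozzle compensation."""

import numpy as np
import pytest
import trimesh

from anisoslice import (
    DepositionParams,
    HeightField,
    ValidationError,
    adjust_nozzle_height,
    conformal_layers,
    flow_rate,
    heightfield_from_points,
    layer_contour,
    load_mesh,
    make_incline,
    make_paraboloid,
    path_gradient,
    project_to_surface,
    reorient_min_height,
    split_top_bottom,
    write_mesh,
)
from anisoslice.geometry import MeshLoadError

UNIT_SQUARE_STL = """solid square
facet normal 0 0 1
 outer loop
  vertex 0 0 0
  vertex 1 0 0
  vertex 1 1 0
 endloop
endfacet
facet normal 0 0 1
 outer loop
  vertex 0 0 0
  vertex 1 1 0
  vertex 0 1 0
 endloop
endfacet
endsolid square
"""


class TestMeshIO:
    def test_minimal_ascii_stl(self, tmp_path):
        p = tmp_path / "square.stl"
        p.write_text(UNIT_SQUARE_STL)
        mesh = load_mesh(p)
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 2

    def test_write_read_round_trip_preserves_vertices(self, tmp_path):
        mesh = make_paraboloid(extent=10, curvature=0.02, resolution=9)
        p = tmp_path / "p.stl"
        write_mesh(mesh, p)
        back = load_mesh(p)
        a = np.array(sorted(map(tuple, np.round(mesh.vertices, 6))))
        b = np.array(sorted(map(tuple, np.round(back.vertices, 6))))
        assert np.allclose(a, b, atol=1e-6)

    def test_fixture_paraboloid_counts(self):
        mesh = make_paraboloid(resolution=41)
        assert len(mesh.vertices) == 1681
        assert len(mesh.faces) == 3200

    def test_malformed_stl_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"not an stl at all \x00\x01\x02")
        with pytest.raises(MeshLoadError):
            load_mesh(p)


class TestReorient:
    def test_idempotent_on_minimal_height_mesh(self):
        mesh = trimesh.creation.box(extents=[10, 10, 1])
        out, rot = reorient_min_height(mesh)
        z = np.asarray(out.vertices)[:, 2]
        assert z.max() - z.min() == pytest.approx(1.0, abs=1e-9)
        assert rot.rx == 0.0 and rot.ry == 0.0

    @pytest.mark.parametrize("tilt", [10.0, 30.0])
    def test_recovers_tilted_plate(self, tilt):
        mesh = trimesh.creation.box(extents=[10, 10, 1])
        mesh.apply_transform(
            trimesh.transformations.rotation_matrix(np.deg2rad(tilt), [1, 0, 0]))
        out, _ = reorient_min_height(mesh)
        z = np.asarray(out.vertices)[:, 2]
        assert z.max() - z.min() == pytest.approx(1.0, abs=0.05)

    def test_sphere_extent_invariant(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        out, _ = reorient_min_height(mesh, step_deg=5.0)
        z = np.asarray(out.vertices)[:, 2]
        assert z.max() - z.min() == pytest.approx(10.0, rel=0.02)

    def test_never_increases_height(self):
        mesh = make_paraboloid(extent=20, curvature=0.01, resolution=15)
        before = np.ptp(np.asarray(mesh.vertices)[:, 2])
        out, _ = reorient_min_height(mesh, step_deg=5.0)
        after = np.ptp(np.asarray(out.vertices)[:, 2])
        assert after <= before + 1e-9


class TestSplitTopBottom:
    def test_horizontal_plate_partition(self):
        mesh = trimesh.creation.box(extents=[4, 4, 1])
        r = split_top_bottom(mesh)
        nz = np.asarray(mesh.vertex_normals)[:, 2]
        assert set(r.bottom_vertices) == set(np.flatnonzero(nz < 0))
        assert set(r.top_vertices) == set(np.flatnonzero(nz >= 0))

    def test_matches_brute_force_on_shell(self):
        mesh = make_paraboloid(extent=20, curvature=0.02, resolution=15)
        r = split_top_bottom(mesh)
        nz = np.asarray(mesh.vertex_normals)[:, 2]
        expect_bottom = np.flatnonzero((nz < 0) & (np.abs(nz) >= 1e-6))
        assert np.array_equal(np.sort(r.bottom_vertices), expect_bottom)
        assert len(r.bottom_vertices) + len(r.top_vertices) == len(mesh.vertices)

    def test_vertical_walls_counted_in_warning(self):
        # an open vertical quad: all normals horizontal
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        with pytest.warns(UserWarning, match="near-vertical"):
            r = split_top_bottom(mesh)
        assert r.n_ambiguous == 4
        assert len(r.bottom_vertices) == 0


class TestHeightField:
    def test_exact_on_linear_field(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, size=(60, 2))
        pts = np.column_stack([xy, 2 * xy[:, 0] + 3 * xy[:, 1]])
        hf = heightfield_from_points(pts, spacing=0.5)
        x, y = 4.3, 5.1
        assert hf.sample(x, y) == pytest.approx(2 * x + 3 * y, abs=1e-9)

    def test_second_order_accuracy_on_paraboloid(self):
        g = np.linspace(-10, 10, 81)
        X, Y = np.meshgrid(g, g)
        c = 0.01
        pts = np.column_stack([X.ravel(), Y.ravel(), (c * (X**2 - Y**2)).ravel()])
        hf = heightfield_from_points(pts, spacing=0.25)
        xs = np.linspace(-8, 8, 33)
        zs = np.array([hf.sample(x, 3.3) for x in xs])
        err = np.abs(zs - c * (xs**2 - 3.3**2))
        h = 0.25  # interpolation error bound ~ c * h^2 for curvature 2c
        assert err.max() < 4 * c * h**2 + 1e-9

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
        with pytest.raises(ValidationError):
            heightfield_from_points(pts, spacing=0.5)

    def test_zero_spacing_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(ValidationError):
            heightfield_from_points(pts, spacing=0.0)


class TestConformalLayers:
    def _flat(self, z=0.0):
        return HeightField(origin=(0.0, 0.0), spacing=1.0, z=np.full((5, 5), z))

    def test_flat_base_cumulative_offsets(self):
        layers = conformal_layers(self._flat(), [("bottom_cover", 0.42)] * 3)
        assert [l.offset for l in layers] == pytest.approx([0.42, 0.84, 1.26])

    def test_cric_plan_offsets_and_roles(self):
        plan = [("bottom_cover", 0.6), ("infill", 0.84), ("infill", 0.42),
                ("top_cover", 0.6)]
        layers = conformal_layers(self._flat(), plan)
        assert [l.role for l in layers] == [r for r, _ in plan]
        assert [l.offset for l in layers] == pytest.approx(
            np.cumsum([t for _, t in plan]).tolist())

    def test_curved_base_layers_are_vertical_translations(self):
        z = np.fromfunction(lambda i, j: 0.05 * (i - 2) ** 2, (6, 6))
        base = HeightField(origin=(0, 0), spacing=1.0, z=z)
        layers = conformal_layers(base, [("infill", 0.42), ("infill", 0.42)])
        xs, ys = np.meshgrid(np.linspace(0.5, 4.5, 5), np.linspace(0.5, 4.5, 5))
        d = (np.array([layers[1].sample(x, y) for x, y in zip(xs.ravel(), ys.ravel())])
             - np.array([layers[0].sample(x, y) for x, y in zip(xs.ravel(), ys.ravel())]))
        assert np.allclose(d, 0.42, atol=1e-12)

    def test_layers_commute_with_xy_translation(self):
        z = np.fromfunction(lambda i, j: 0.1 * j, (5, 5))
        base = HeightField(origin=(0, 0), spacing=1.0, z=z)
        moved = base.translated(3.0, -2.0)
        l1 = conformal_layers(base, [("infill", 0.5)])[0]
        l2 = conformal_layers(moved, [("infill", 0.5)])[0]
        assert l2.sample(4.2, -0.9) == pytest.approx(l1.sample(1.2, 1.1), abs=1e-12)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValidationError):
            conformal_layers(self._flat(), [])


class TestContourAndProjection:
    def test_extruded_square_contour(self):
        mesh = trimesh.creation.box(extents=[10, 10, 2])
        base = HeightField(origin=(-5, -5), spacing=1.0, z=np.full((11, 11), -1.0))
        layer = conformal_layers(base, [("infill", 0.5)])[0]
        polys = layer_contour(mesh, layer)
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(100.0, rel=1e-9)
        assert polys[0].exterior.is_ccw

    def test_contour_area_matches_rasterization(self):
        mesh = make_paraboloid(extent=20, curvature=0.01, resolution=15)
        base = HeightField(origin=(-10, -10), spacing=1.0, z=np.full((21, 21), 0.0))
        layer = conformal_layers(base, [("infill", 0.5)])[0]
        polys = layer_contour(mesh, layer)
        area = sum(p.area for p in polys)
        # brute-force rasterized footprint of the projected triangles
        import shapely
        from shapely.geometry import Polygon as SPoly
        from shapely.ops import unary_union
        tris = np.asarray(mesh.vertices)[np.asarray(mesh.faces)][:, :, :2]
        u = unary_union([SPoly(t) for t in tris])
        cell = 0.05
        g = np.arange(-10.5 + cell / 2, 10.5, cell)
        X, Y = np.meshgrid(g, g)
        raster = cell**2 * np.count_nonzero(shapely.contains_xy(u, X.ravel(), Y.ravel()))
        assert area == pytest.approx(raster, rel=0.01)

    def test_layer_above_mesh_is_empty(self):
        mesh = trimesh.creation.box(extents=[10, 10, 2])
        base = HeightField(origin=(-5, -5), spacing=1.0, z=np.full((11, 11), -1.0))
        layer = conformal_layers(base, [("infill", 10.0)])[0]
        assert layer_contour(mesh, layer) == []

    def test_projection_on_flat_and_inclined_layers(self):
        flat = HeightField(origin=(0, 0), spacing=1.0, z=np.full((4, 4), 1.2))
        layer = conformal_layers(flat, [("infill", 0.0001)])[0]
        path = project_to_surface(np.array([[0.5, 0.5], [2.0, 1.0]]), layer)
        assert np.allclose(path[:, 2], 1.2 + 0.0001)
        plane = HeightField(origin=(0, 0), spacing=0.5,
                            z=np.fromfunction(lambda i, j: 2 * 0.5 * j, (7, 7)))
        layer2 = conformal_layers(plane, [("infill", 1e-9)])[0]
        p = project_to_surface(np.array([[0.5, 0.0]]), layer2)
        assert p[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_out_of_region_waypoint_names_index(self):
        flat = HeightField(origin=(0, 0), spacing=1.0, z=np.full((4, 4), 0.0))
        layer = conformal_layers(flat, [("infill", 0.5)])[0]
        with pytest.raises(ValidationError, match="waypoint 1"):
            project_to_surface(np.array([[0.5, 0.5], [99.0, 0.5]]), layer)


class TestPathGradient:
    def test_horizontal_path_zero_alpha(self):
        p = np.column_stack([np.linspace(0, 10, 11), np.zeros(11), np.ones(11)])
        alpha, _ = path_gradient(p)
        assert np.allclose(alpha, 0.0)

    def test_unit_ramp_is_45_degrees_ascending(self):
        t = np.linspace(0, 10, 21)
        p = np.column_stack([t, np.zeros_like(t), t])
        alpha, sense = path_gradient(p)
        assert np.allclose(alpha, 45.0, atol=1e-9)
        assert all(s == "ascending" for s in sense)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.linspace(0, 20, 401)
        z = 2.0 * np.sin(0.5 * t)
        p = np.column_stack([t, np.zeros_like(t), z])
        alpha, _ = path_gradient(p)
        expect = np.rad2deg(np.arctan(np.abs(np.cos(0.5 * t))))
        assert np.max(np.abs(alpha[1:-1] - expect[1:-1])) < 0.2

    def test_incline_fixture_gradient_round_trip(self):
        # cross-module: a path on the 30-degree incline reports alpha = 30
        mesh = make_incline(alpha=30.0, extent=20, resolution=11)
        pts = np.asarray(mesh.vertices)
        hf = heightfield_from_points(pts, spacing=1.0)
        layer = conformal_layers(hf, [("infill", 1e-9)])[0]
        xy = np.column_stack([np.linspace(-8, 8, 17), np.zeros(17)])
        p3 = project_to_surface(xy, layer)
        alpha, sense = path_gradient(p3)
        assert np.allclose(alpha[1:-1], 30.0, atol=0.5)
        assert all(s == "ascending" for s in sense)

    def test_duplicate_waypoints_rejected(self):
        p = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(ValidationError, match="duplicate"):
            path_gradient(p)


class TestNozzleCompensation:
    def test_zero_inclination_identity(self):
        for sense in ("ascending", "descending"):
            p = DepositionParams(h0=0.42, d=0.84, alpha=0.0, travel_sense=sense)
            assert adjust_nozzle_height(p) == pytest.approx(0.42, abs=1e-12)

    def test_hand_computed_45_degree_case(self):
        down = DepositionParams(h0=0.42, d=0.84, alpha=45.0, travel_sense="descending")
        up = DepositionParams(h0=0.42, d=0.84, alpha=45.0, travel_sense="ascending")
        assert adjust_nozzle_height(down) == pytest.approx(
            0.42 / np.cos(np.deg2rad(45)) + 0.42, abs=1e-4)
        assert adjust_nozzle_height(down) == pytest.approx(1.0140, abs=1e-4)
        assert adjust_nozzle_height(up) == pytest.approx(0.1740, abs=1e-4)

    def test_branches_symmetric_about_secant_term(self):
        for a in (10.0, 25.0, 40.0):
            down = adjust_nozzle_height(
                DepositionParams(h0=0.42, d=0.84, alpha=a, travel_sense="descending"))
            up = adjust_nozzle_height(
                DepositionParams(h0=0.42, d=0.84, alpha=a, travel_sense="ascending"))
            mid = 0.42 / np.cos(np.deg2rad(a))
            assert down - mid == pytest.approx(mid - up, abs=1e-12)

    def test_divergence_grows_with_inclination(self):
        alphas = np.linspace(0, 60, 13)
        downs = [adjust_nozzle_height(DepositionParams(
            h0=0.42, d=0.84, alpha=a, travel_sense="descending")) for a in alphas]
        assert np.all(np.diff(downs) > 0)

    def test_alpha_at_90_rejected(self):
        with pytest.raises(ValidationError):
            DepositionParams(h0=0.42, d=0.84, alpha=90.0, travel_sense="ascending")


class TestFlowRate:
    def test_reference_operating_point(self):
        assert flow_rate(16.667, 0.84, 0.42) == pytest.approx(
            16.667 * 0.84 * 0.42, rel=1e-12)

    def test_linear_in_height_and_zero_speed(self):
        assert flow_rate(10, 0.84, 0.84) == pytest.approx(2 * flow_rate(10, 0.84, 0.42))
        assert flow_rate(0.0, 0.84, 0.42) == 0.0
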