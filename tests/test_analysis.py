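import numpy as np
import pytest

import oracles
from vessel3d import shapes
from vessel3d.analysis import (
    COLOR_DARK_BLUE,
    COLOR_GREEN,
    COLOR_LIGHT_BLUE,
    COLOR_RED,
    classify_connectivity,
    colorize_sdf,
    connected_components,
    diagonal_fraction_threshold,
    filter_components,
    largest_diameter,
    remove_interior,
    shape_diameter,
    volumetric_obscurance,
)
from vessel3d.io import SurfaceMesh


def merge(meshes):
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return SurfaceMesh(np.concatenate(verts), np.concatenate(faces))


class TestConnectedComponents:
    def test_two_disjoint_spheres(self):
        m = merge([shapes.sphere(10), shapes.sphere(10, center=(50, 0, 0))])
        comps = connected_components(m)
        assert comps.n_components == 2
        assert comps.vertex_counts.sum() == m.n_vertices

    def test_empty_mesh(self):
        comps = connected_components(SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int)))
        assert comps.n_components == 0

    def test_matches_union_find_oracle(self, rng):
        # random triangle soup over a shared vertex pool
        nv = 90
        verts = rng.normal(size=(nv, 3)) * 20
        faces = rng.integers(0, nv, (200, 3))
        faces = faces[(faces[:, 0] != faces[:, 1])
                      & (faces[:, 1] != faces[:, 2])
                      & (faces[:, 0] != faces[:, 2])]
        m = SurfaceMesh(verts, faces)
        comps = connected_components(m)
        ref = oracles.union_find_components(faces, nv)
        # same partition up to relabeling
        for label_pair in ((comps.component_id, ref), (ref, comps.component_id)):
            mapping = {}
            for a, b in zip(*label_pair):
                if a < 0:
                    assert b < 0
                    continue
                assert mapping.setdefault(a, b) == b


class TestLargestDiameter:
    def test_box_diagonal(self):
        import trimesh

        tm = trimesh.creation.box(extents=(10, 20, 30))
        d = largest_diameter(np.asarray(tm.vertices))
        assert d == pytest.approx(np.sqrt(10**2 + 20**2 + 30**2), abs=1e-9)

    def test_sphere_diameter(self):
        s = shapes.sphere(70, subdivisions=4)
        assert largest_diameter(s.vertices) == pytest.approx(70, abs=0.5)

    def test_single_point(self):
        assert largest_diameter(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_hull_path_equals_pairwise(self, rng):
        pts = rng.normal(size=(6000, 3)) * 30  # > 5000 triggers the hull path
        from scipy.spatial.distance import pdist

        assert largest_diameter(pts) == pytest.approx(pdist(pts).max(), rel=1e-12)


class TestFilterComponents:
    def test_70um_cutoff_keeps_only_large(self):
        small = shapes.sphere(60)
        large = shapes.sphere(80, center=(200, 0, 0))
        m = merge([small, large])
        comps = connected_components(m)
        out = filter_components(m, comps, 70.0)
        assert out.n_vertices == large.n_vertices
        assert out.vertices[:, 0].min() > 100

    def test_zero_cutoff_is_identity(self):
        m = merge([shapes.sphere(5), shapes.sphere(9, center=(30, 0, 0))])
        comps = connected_components(m)
        out = filter_components(m, comps, 0.0)
        assert out.n_vertices == m.n_vertices
        assert out.n_faces == m.n_faces

    def test_many_blobs_match_brute_force(self, rng):
        diams = rng.uniform(30, 110, size=40)
        meshes, centers = [], []
        for i, d in enumerate(diams):
            c = (i % 8 * 150, i // 8 * 150, 0)
            meshes.append(shapes.sphere(d, subdivisions=1, center=c))
            centers.append(c)
        m = merge(meshes)
        comps = connected_components(m)
        out = filter_components(m, comps, 70.0)
        # brute force: exact diameter of each blob decides survival
        expected = 0
        for mesh, d in zip(meshes, diams):
            exact = largest_diameter(mesh.vertices)
            if exact >= 70.0:
                expected += mesh.n_vertices
        assert out.n_vertices == expected


class TestDiagonalFraction:
    def test_full_roi_thresholds(self):
        assert diagonal_fraction_threshold((980, 980, 140), 0.05) == 70.0
        assert diagonal_fraction_threshold((980, 980, 140), 0.005) == 7.0

    @pytest.mark.parametrize("extent,frac", [((1, 0, 1), 0.05), ((10, 10, 10), 0.0),
                                             ((10, 10, 10), 1.5)])
    def test_invalid_inputs_raise(self, extent, frac):
        with pytest.raises(ValueError):
            diagonal_fraction_threshold(extent, frac)


class TestObscuranceAndInterior:
    def test_isolated_sphere_surface_half_visible(self):
        s = shapes.sphere(30, subdivisions=3)
        obs = volumetric_obscurance(s, 32)
        assert np.median(obs) == pytest.approx(0.5, abs=0.1)

    def test_hollow_sphere_inner_shell_enclosed(self):
        hs = shapes.hollow_sphere(40, 30)
        obs = volumetric_obscurance(hs, 24)
        inner = np.linalg.norm(hs.vertices, axis=1) < 17.5
        assert obs[inner].max() == 0.0
        assert obs[~inner].min() > 0.2

    def test_flat_plate_half_visible_both_sides(self):
        p = shapes.plate(60, 60, 4)
        obs = volumetric_obscurance(p, 32)
        broad = np.abs(np.abs(p.vertices[:, 2]) - 2) < 1e-9
        inner = (np.abs(p.vertices[:, 0]) < 20) & (np.abs(p.vertices[:, 1]) < 20)
        assert np.median(obs[broad & inner]) == pytest.approx(0.5, abs=0.12)

    def test_remove_interior_strips_inner_shell_only(self):
        hs = shapes.hollow_sphere(40, 30)
        obs = volumetric_obscurance(hs, 24)
        out = remove_interior(hs, obs, 0.05)
        assert (np.linalg.norm(out.vertices, axis=1) > 17.5).all()
        n_outer = (np.linalg.norm(hs.vertices, axis=1) > 17.5).sum()
        assert out.n_vertices == n_outer

    def test_solid_sphere_unchanged(self):
        s = shapes.sphere(30)
        obs = volumetric_obscurance(s, 24)
        out = remove_interior(s, obs, 0.05)
        assert out.n_vertices == s.n_vertices

    def test_threshold_zero_is_identity(self):
        hs = shapes.hollow_sphere(40, 30)
        out = remove_interior(hs, np.zeros(hs.n_vertices), 0.0)
        assert out.n_vertices == hs.n_vertices

    def test_cut_surface_vertices_protected(self):
        hs = shapes.hollow_sphere(40, 30)
        hs.vertex_attrs["cut_surface"] = np.ones(hs.n_vertices, np.uint8)
        out = remove_interior(hs, np.zeros(hs.n_vertices), 0.05)
        assert out.n_vertices == hs.n_vertices


class TestShapeDiameter:
    def test_cylinder_reads_its_diameter(self):
        t = shapes.tube(radius=10, height=200, n_z=41)
        f = shape_diameter(t)
        side = np.abs(t.vertices[:, 2]) < 80
        vals = f.values[side & f.valid]
        assert np.median(vals) == pytest.approx(20, rel=0.10)

    def test_sphere_reads_its_diameter(self):
        s = shapes.sphere(40)
        f = shape_diameter(s)
        assert np.median(f.values[f.valid]) == pytest.approx(40, rel=0.10)

    def test_flat_plate_reads_thickness(self):
        # a broad flat sinus viewed from its broad side legitimately reads thin
        p = shapes.plate(60, 60, 4)
        f = shape_diameter(p)
        broad = np.abs(np.abs(p.vertices[:, 2]) - 2) < 1e-9
        inner = (np.abs(p.vertices[:, 0]) < 20) & (np.abs(p.vertices[:, 1]) < 20)
        assert np.median(f.values[broad & inner]) == pytest.approx(4, rel=0.10)

    def test_scaling_linearity(self):
        t = shapes.tube(radius=8, height=100, n_z=21)
        f1 = shape_diameter(t)
        t2 = SurfaceMesh(t.vertices * 2, t.faces)
        f2 = shape_diameter(t2)
        ok = f1.valid & f2.valid
        ratio = f2.values[ok] / f1.values[ok]
        assert np.median(np.abs(ratio - 2.0)) < 0.02

    def test_robust_variant_and_bad_aggregate(self):
        s = shapes.sphere(40)
        f = shape_diameter(s, aggregate="robust")
        assert np.median(f.values[f.valid]) == pytest.approx(40, rel=0.10)
        with pytest.raises(ValueError):
            shape_diameter(s, aggregate="mean")


class TestColorizeSdf:
    def test_threshold_colors(self):
        vals = np.array([10.0, 35.0, 16.5, 12.0, 30.0])
        rgb = colorize_sdf(vals)
        np.testing.assert_array_equal(rgb[0], [255, 0, 0])      # below 12: red
        np.testing.assert_array_equal(rgb[1], [0, 255, 0])      # above 30: green
        np.testing.assert_array_equal(rgb[2], [128, 128, 0])    # centre: 50/50 blend
        np.testing.assert_array_equal(rgb[3], [255, 0, 0])      # ramp start
        np.testing.assert_array_equal(rgb[4], [0, 255, 0])      # ramp end

    def test_gradient_monotone_between_low_and_high(self):
        vals = np.linspace(12, 30, 50)
        rgb = colorize_sdf(vals).astype(int)
        assert (np.diff(rgb[:, 0]) <= 0).all()  # red falls
        assert (np.diff(rgb[:, 1]) >= 0).all()  # green rises


class TestClassifyConnectivity:
    def _scene(self):
        return {
            5: shapes.sphere(5, center=(0, 0, 0)),
            15: shapes.sphere(15, center=(100, 0, 0)),
            100: shapes.sphere(100, subdivisions=2, center=(300, 0, 0)),
            400: shapes.sphere(400, subdivisions=2, center=(900, 0, 0)),
        }

    def test_threshold_class_mapping(self):
        scene = self._scene()
        m = merge(scene.values())
        comps = connected_components(m)
        out, ids, classes = classify_connectivity(m, comps, 7.0, 28.0, n_large=1)
        # 5 um blob discarded
        assert out.n_vertices == m.n_vertices - scene[5].n_vertices
        by_diam = {round(comps.largest_diameters[c]): cls for c, cls in classes.items()}
        assert by_diam[5] == "discarded"
        assert by_diam[15] == "small"
        assert by_diam[100] == "network"
        assert by_diam[400] == "largest"
        # colors follow the classes
        x = out.vertices[:, 0]
        np.testing.assert_array_equal(out.colors[(x > 50) & (x < 200)][0], COLOR_RED)
        np.testing.assert_array_equal(out.colors[(x > 200) & (x < 500)][0], COLOR_GREEN)
        np.testing.assert_array_equal(out.colors[x > 600][0], COLOR_LIGHT_BLUE)

    def test_ten_similar_networks_rank_light_plus_dark_blue(self):
        meshes = [shapes.sphere(100 + i, subdivisions=1, center=(i * 300, 0, 0))
                  for i in range(10)]
        m = merge(meshes)
        comps = connected_components(m)
        out, _, classes = classify_connectivity(m, comps, 7.0, 28.0, n_large=10)
        ranks = list(classes.values())
        assert ranks.count("largest") == 1
        assert ranks.count("runner_up") == 9
        colors = {tuple(c) for c in np.unique(out.colors, axis=0)}
        assert tuple(COLOR_LIGHT_BLUE) in colors and tuple(COLOR_DARK_BLUE) in colors

    def test_empty_mesh(self):
        m = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int))
        out, ids, classes = classify_connectivity(m, connected_components(m))
        assert out.is_empty and classes == {}

    def test_invalid_n_large(self):
        m = shapes.sphere(50)
        with pytest.raises(ValueError):
            classify_connectivity(m, connected_components(m), n_large=0)
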