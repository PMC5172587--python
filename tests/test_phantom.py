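import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi

from vessel3d.colorflow import extract_saturation
from vessel3d.phantom import (
    DefectRates,
    PhantomSpec,
    PhantomTruth,
    RecoveryReport,
    evaluate_recovery,
    generate_network,
    rasterize_truth,
    render_sections,
    truth_from_json,
    truth_to_json,
)

CLEAN = DefectRates(0.0, 0.0, 0.0)


def graphs_identical(g1, g2):
    if set(g1.edges) != set(g2.edges) or set(g1.nodes) != set(g2.nodes):
        return False
    p1 = nx.get_node_attributes(g1, "pos")
    p2 = nx.get_node_attributes(g2, "pos")
    return all(np.allclose(p1[n], p2[n]) for n in p1)


class TestGenerateNetwork:
    def test_seeded_determinism(self):
        spec = PhantomSpec(seed=1, defect_rates=CLEAN)
        t1, t2 = generate_network(spec), generate_network(spec)
        assert graphs_identical(t1.graph, t2.graph)

    def test_disjoint_networks_without_cross_links(self):
        spec = PhantomSpec(seed=2, n_capillary_networks=1, n_sinus_networks=1,
                           n_cross_connections=0, defect_rates=CLEAN)
        t = generate_network(spec)
        assert nx.number_connected_components(t.graph) == 2
        assert t.n_networks == 2

    def test_cross_link_merges_components(self):
        spec = PhantomSpec(seed=2, n_capillary_networks=1, n_sinus_networks=1,
                           n_cross_connections=1, defect_rates=CLEAN)
        t = generate_network(spec)
        # union-find oracle over edge endpoints
        import oracles

        edges = np.array([(u, v, v) for u, v in t.graph.edges])
        labels = oracles.union_find_components(edges, max(t.graph.nodes) + 1)
        n_comp = len(set(labels[labels >= 0]))
        assert n_comp == 1
        assert nx.number_connected_components(t.graph) == 1

    def test_diameters_within_class_ranges(self):
        spec = PhantomSpec(seed=3, defect_rates=CLEAN)
        t = generate_network(spec)
        for _, _, d in t.graph.edges(data=True):
            lo, hi = (spec.capillary_diam_range if d["vessel_class"] == "capillary"
                      else spec.sinus_diam_range)
            assert lo <= d["diameter"] <= hi

    def test_centerlines_inside_domain(self):
        spec = PhantomSpec(seed=4, defect_rates=CLEAN)
        t = generate_network(spec)
        pos = np.array(list(nx.get_node_attributes(t.graph, "pos").values()))
        assert (pos >= 0).all()
        assert (pos <= np.asarray(spec.domain_size)).all()

    def test_domain_too_small_raises(self):
        with pytest.raises(ValueError):
            generate_network(PhantomSpec(domain_size=(30.0, 30.0, 30.0), seed=1))

    def test_overlapping_class_ranges_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(capillary_diam_range=(2, 35), sinus_diam_range=(30, 60))


class TestRasterizeTruth:
    def _single_edge_truth(self, diam, p0, p1, domain=(60.0, 60.0, 60.0), wall=1.5):
        g = nx.Graph()
        g.add_node(0, pos=np.asarray(p0, float))
        g.add_node(1, pos=np.asarray(p1, float))
        g.add_edge(0, 1, diameter=diam, vessel_class="capillary", network_id=0,
                   flatness=1.0)
        spec = PhantomSpec(domain_size=domain, wall_thickness=wall,
                           defect_rates=CLEAN, seed=0)
        return PhantomTruth(g, [], spec)

    def test_straight_capillary_ring_cross_section(self):
        truth = self._single_edge_truth(10.0, (30, 30, 5), (30, 30, 55))
        vol = rasterize_truth(truth, (0.5, 0.5, 0.5))
        mid = vol.data[60]  # z = 30 um
        ys, xs = np.nonzero(mid)
        r = np.sqrt((ys - 60) ** 2 + (xs - 60) ** 2) * 0.5
        assert r.max() == pytest.approx(5.0, abs=0.5)       # outer radius
        assert r.min() == pytest.approx(3.5, abs=0.5)       # inner radius (wall 1.5)
        assert mid[60, 60] == 0                              # lumen open

    def test_empty_truth_all_zero(self):
        g = nx.Graph()
        spec = PhantomSpec(defect_rates=CLEAN, seed=0)
        vol = rasterize_truth(PhantomTruth(g, [], spec), (1, 1, 1))
        assert (vol.data == 0).all()

    def test_cell_sphere_equatorial_disk(self):
        g = nx.Graph()
        spec = PhantomSpec(domain_size=(40.0, 40.0, 40.0), defect_rates=CLEAN, seed=0)
        truth = PhantomTruth(g, [(np.array([20.0, 20.0, 20.0]), 8.0)], spec)
        vol = rasterize_truth(truth, (0.5, 0.5, 0.5))
        eq = vol.data[40]
        ys, xs = np.nonzero(eq)
        assert (xs.max() - xs.min() + 1) == pytest.approx(16, abs=1)
        assert eq[40, 40] > 0  # filled, not a shell


class TestRenderSections:
    def test_inclusive_slice_count(self):
        spec = PhantomSpec(seed=5, defect_rates=CLEAN)  # z extent 140 um
        t = generate_network(spec)
        stack = render_sections(t, xy_spacing=1.4, z_spacing=7.0)
        assert stack.n_slices == 21

    def test_byte_identical_across_runs(self):
        spec = PhantomSpec(seed=6, defect_rates=CLEAN)
        t = generate_network(spec)
        a = render_sections(t, xy_spacing=2.0, z_spacing=14.0)
        b = render_sections(t, xy_spacing=2.0, z_spacing=14.0)
        for sa, sb in zip(a.slices, b.slices):
            assert sa.tobytes() == sb.tobytes()

    def test_clean_render_matches_rasterized_truth(self):
        spec = PhantomSpec(seed=7, defect_rates=CLEAN)
        t = generate_network(spec)
        stack = render_sections(t, xy_spacing=0.7, z_spacing=7.0)
        sat = extract_saturation(stack)
        pred = sat.data >= 70
        truth_vol = rasterize_truth(t, (7.0, 0.7, 0.7))
        ref = truth_vol.data > 0
        iou = (pred & ref).sum() / (pred | ref).sum()
        assert iou >= 0.85

    def test_z_spacing_below_xy_rejected(self):
        spec = PhantomSpec(seed=1, defect_rates=CLEAN)
        t = generate_network(spec)
        with pytest.raises(ValueError):
            render_sections(t, xy_spacing=7.0, z_spacing=1.0)

    def test_collapse_fraction_monotone_fragmentation(self):
        """More collapsed capillaries can only fragment the thresholded
        capillary signal further, never heal it."""
        spec0 = PhantomSpec(seed=11, n_capillary_networks=1, n_sinus_networks=0,
                            defect_rates=CLEAN)
        counts = []
        for frac in (0.0, 0.5, 1.0):
            spec = PhantomSpec(seed=11, n_capillary_networks=1, n_sinus_networks=0,
                               defect_rates=DefectRates(0.0, frac, 0.0))
            t = generate_network(spec)
            stack = render_sections(t, xy_spacing=1.0, z_spacing=7.0)
            sat = extract_saturation(stack)
            n = ndi.label(sat.data >= 70)[1]
            counts.append(n)
        assert counts[0] <= counts[1] <= counts[2]


class TestTruthJson:
    def test_round_trip(self):
        spec = PhantomSpec(seed=8, defect_rates=DefectRates(0.5, 0.1, 2000.0))
        t = generate_network(spec)
        back = truth_from_json(truth_to_json(t), spec)
        assert graphs_identical(t.graph, back.graph)
        assert len(back.cells) == len(t.cells)


class TestEvaluateRecovery:
    def test_empty_mesh_reports_zero(self):
        spec = PhantomSpec(seed=9, defect_rates=CLEAN)
        t = generate_network(spec)
        rep = evaluate_recovery(t, None, np.zeros(0, int), np.zeros(0))
        assert rep.n_found_networks == 0
        assert rep.vertex_class_accuracy == 0.0
        assert not rep.topology_match

    def test_rasterized_truth_surface_classifies_correctly(self):
        """Meshing the rasterized truth directly (no filtering) and using the
        true local diameters as the SDF recovers the caliber classes."""
        from vessel3d.meshing import extract_isosurface
        from vessel3d.analysis import connected_components

        spec = PhantomSpec(seed=10, n_capillary_networks=1, n_sinus_networks=1,
                           sinus_flatness_max=1.0, defect_rates=CLEAN)
        t = generate_network(spec)
        vol = rasterize_truth(t, (1.0, 1.0, 1.0))
        mesh = extract_isosurface(vol, 127.5)
        comps = connected_components(mesh)
        # oracle SDF: diameter of the nearest truth edge
        from scipy.spatial import cKDTree
        from vessel3d.phantom import _truth_samples

        pts, classes, nets, diams = _truth_samples(t)
        _, nearest = cKDTree(pts).query(mesh.vertices)
        sdf = diams[nearest]
        rep = evaluate_recovery(t, mesh, comps.component_id, sdf)
        assert rep.vertex_class_accuracy >= 0.9

    def test_accuracy_bounds_enforced(self):
        with pytest.raises(ValueError):
            RecoveryReport(1, 1, 1.5, [], True)
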