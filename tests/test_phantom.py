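"""Phantom generator: network growth, rasterization, leakage simulation."""

import numpy as np
import pytest

from vasomet import phantom
from vasomet.phantom import PhantomError, PhantomSpec


class TestSpecValidation:
    def test_timepoints_must_increase(self):
        with pytest.raises(PhantomError):
            PhantomSpec(timepoints_min=(5.0, 5.0))
        with pytest.raises(PhantomError):
            PhantomSpec(timepoints_min=(10.0, 5.0))

    def test_negative_rates_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(clearance_rate_kc=-0.1)

    def test_defaults_match_acquisition_protocol(self):
        spec = PhantomSpec()
        assert spec.frame_shape == (512, 512)
        assert spec.n_layers == 5
        assert spec.layer_spacing_um == 1.0
        assert spec.timepoints_min == tuple(float(t) for t in range(5, 65, 5))
        labels = [c[0] for c in spec.tracer_channels]
        assert labels == ["FITC40", "TRITC70"]


class TestBuildNetwork:
    def test_single_segment_no_branching(self, flat_spec):
        g = phantom.build_network(flat_spec, n_segments=1, branch_prob=0.0)
        assert len(g.edges) == 1
        assert g.branch_count == 0

    def test_determinism(self, flat_spec):
        g1 = phantom.build_network(flat_spec, n_segments=5, seed=3)
        g2 = phantom.build_network(flat_spec, n_segments=5, seed=3)
        assert len(g1.edges) == len(g2.edges)
        for e1, e2 in zip(g1.edges, g2.edges):
            np.testing.assert_array_equal(e1.polyline_um, e2.polyline_um)
            assert e1.radius_um == e2.radius_um
            assert e1.permeability_per_min == e2.permeability_per_min

    def test_branch_count_matches_degree_census(self, flat_spec):
        """Declared branch count equals an exhaustive degree scan."""
        g = phantom.build_network(flat_spec, n_segments=6, branch_prob=1.0,
                                  seed=5)
        deg = np.zeros(len(g.nodes), dtype=int)
        for e in g.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        assert g.branch_count == int((deg >= 3).sum())
        assert g.branch_count >= 1  # branching forced

    def test_oversized_radius_rejected(self, flat_spec):
        with pytest.raises(PhantomError, match="radius_range"):
            phantom.build_network(flat_spec, radius_range=(3.0, 60.0))

    def test_polylines_inside_bounding_box(self, flat_spec):
        g = phantom.build_network(flat_spec, n_segments=6, seed=2)
        box = np.asarray(g.bounding_box_um)
        for e in g.edges:
            assert np.all(e.polyline_um >= -1e-9)
            assert np.all(e.polyline_um <= box + 1e-9)


class TestRasterize:
    def test_tube_cross_section_thickness(self, flat_spec):
        """Pixel-center rule: radius r at 1 um/px gives 2r+1 thick sections."""
        g = phantom.straight_tube_graph(flat_spec, radius_um=5.0)
        mask = phantom.rasterize(g, flat_spec)[0]
        cols = mask[:, 60:140]
        thickness = cols.sum(axis=0)
        assert np.all(thickness == 11)

    def test_empty_graph_all_zero(self, flat_spec):
        g = phantom.VesselGraph(nodes=[], edges=[],
                                bounding_box_um=flat_spec.extent_um,
                                n_components=0)
        mask = phantom.rasterize(g, flat_spec)
        assert mask.shape == (1, 200, 200)
        assert not mask.any()

    def test_crossing_tubes_union(self, flat_spec):
        ga = phantom.straight_tube_graph(flat_spec, radius_um=5, angle_deg=0)
        gb = phantom.straight_tube_graph(flat_spec, radius_um=4, angle_deg=90)
        both = phantom.VesselGraph(
            nodes=ga.nodes + gb.nodes,
            edges=ga.edges + [phantom.Edge(e.node_a + 2, e.node_b + 2,
                                           e.polyline_um, e.radius_um,
                                           e.permeability_per_min)
                              for e in gb.edges],
            bounding_box_um=flat_spec.extent_um, n_components=2)
        m_union = phantom.rasterize(both, flat_spec)
        m_a = phantom.rasterize(ga, flat_spec)
        m_b = phantom.rasterize(gb, flat_spec)
        np.testing.assert_array_equal(m_union, m_a | m_b)

    @pytest.mark.parametrize("radius", [3.0, 5.0, 8.0])
    def test_tube_area_matches_analytic(self, flat_spec, radius):
        """Digital capsule area vs analytic with the half-pixel band."""
        g = phantom.straight_tube_graph(flat_spec, radius_um=radius,
                                        length_um=120.0)
        mask = phantom.rasterize(g, flat_spec)[0]
        r_eff = radius + 0.5
        analytic = 2 * r_eff * 120.0 + np.pi * r_eff ** 2
        assert abs(mask.sum() - analytic) / analytic < 0.05

    def test_brute_force_voxel_rule(self):
        """A voxel is set iff its center is within radius of the centerline."""
        spec = PhantomSpec(frame_shape=(40, 40), n_layers=3, seed=0)
        g = phantom.straight_tube_graph(spec, radius_um=4.0)
        mask = phantom.rasterize(g, spec)
        poly = g.edges[0].polyline_um
        seg0, seg1 = poly[:-1], poly[1:]
        for iz in range(3):
            for iy in range(40):
                for ix in range(0, 40, 3):  # stride keeps the scan quick
                    p = np.array([iz * spec.layer_spacing_um,
                                  iy * spec.pixel_size_um,
                                  ix * spec.pixel_size_um])
                    d = np.inf
                    for a, b in zip(seg0, seg1):
                        ab = b - a
                        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                        d = min(d, np.linalg.norm(p - (a + t * ab)))
                    assert mask[iz, iy, ix] == (d <= 4.0)


class TestSimulateTimeseries:
    def test_closed_system_constant(self, small_spec):
        """No leakage, no clearance, no noise: every frame identical."""
        import dataclasses

        spec = dataclasses.replace(small_spec, clearance_rate_kc=0.0)
        g = phantom.straight_tube_graph(spec, radius_um=6,
                                        permeability_per_min=0.0)
        stack, truth = phantom.simulate_timeseries(g, spec)
        for ti in range(1, stack.data.shape[0]):
            np.testing.assert_array_equal(stack.data[ti], stack.data[0])
        for curve in truth.oi_curves.values():
            np.testing.assert_allclose(curve, curve[0])

    def test_clearance_closed_form(self):
        """Zero permeability: intravascular decay is exactly exp(-kc*t)."""
        spec = PhantomSpec(frame_shape=(128, 128), n_layers=5, seed=3,
                           timepoints_min=(0.0, 60.0), clearance_rate_kc=0.02,
                           noise_model=(0.0, 0.0))
        g = phantom.straight_tube_graph(spec, radius_um=8,
                                        permeability_per_min=0.0)
        stack, truth = phantom.simulate_timeseries(g, spec)
        mask = truth.true_masks
        i0 = stack.data[0, 0][mask].mean()
        i1 = stack.data[1, 0][mask].mean()
        assert abs(i1 / i0 - np.exp(-1.2)) < 0.01 * np.exp(-1.2)

    def test_size_exclusion_between_channels(self, small_spec):
        """40 kDa channel leaks, 70 kDa (permeability scale 0) does not."""
        g = phantom.straight_tube_graph(small_spec, radius_um=6,
                                        permeability_per_min=0.01)
        _, truth = phantom.simulate_timeseries(g, small_spec)
        d40 = truth.oi_curves["FITC40"][-1] - truth.oi_curves["FITC40"][0]
        d70 = truth.oi_curves["TRITC70"][-1] - truth.oi_curves["TRITC70"][0]
        assert d40 > 0
        assert d70 == 0.0

    def test_bitwise_determinism(self, small_spec):
        g = phantom.build_network(small_spec, n_segments=3, seed=4,
                                  radius_range=(3.0, 6.0))
        s1, t1 = phantom.simulate_timeseries(g, small_spec)
        s2, t2 = phantom.simulate_timeseries(g, small_spec)
        np.testing.assert_array_equal(s1.data, s2.data)
        for ch in t1.oi_curves:
            np.testing.assert_array_equal(t1.oi_curves[ch], t2.oi_curves[ch])

    def test_truth_oi_monotone_without_clearance(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, clearance_rate_kc=0.0)
        g = phantom.straight_tube_graph(spec, radius_um=6,
                                        permeability_per_min=0.01)
        _, truth = phantom.simulate_timeseries(g, spec)
        assert np.all(np.diff(truth.oi_curves["FITC40"]) >= -1e-12)

    def test_delta_strictly_increasing_in_permeability(self, small_spec):
        deltas = []
        for p in (0.003, 0.006, 0.012, 0.024):
            g = phantom.straight_tube_graph(small_spec, radius_um=6,
                                            permeability_per_min=p)
            _, truth = phantom.simulate_timeseries(g, small_spec)
            c = truth.oi_curves["FITC40"]
            deltas.append(c[-1] - c[0])
        assert np.all(np.diff(deltas) > 0)

    def test_diffusion_boundary_mass_budget(self):
        """Closed (reflecting) boundary conserves extravascular mass; the
        open boundary only loses it."""
        rng = np.random.default_rng(0)
        field = np.abs(rng.normal(size=(5, 64, 64)))
        closed = phantom._diffuse(field, (0.5, 1.0, 1.0), "closed")
        assert abs(closed.sum() - field.sum()) / field.sum() < 1e-9
        open_ = phantom._diffuse(field, (0.5, 1.0, 1.0), "open")
        assert open_.sum() < field.sum()
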