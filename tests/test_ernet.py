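"""Graph analysis tests: polygon counting against the face-enumeration
oracle, attachment scoring, and the network diffusion engine."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import chisquare

from ernetics import ernet, synthkit
from ernetics.core import PlanarityError, Roi

from oracles import count_interior_faces, segment_crossings


def graph_from_segments(segs):
    return ernet.ERGraph.from_segments([np.asarray(s, dtype=float)
                                        for s in segs])


class TestCountPolygons:
    def test_triangle_has_one_face(self):
        g = graph_from_segments([[[0, 0], [1, 0]], [[1, 0], [0.5, 1]],
                                 [[0.5, 1], [0, 0]]])
        assert ernet.count_polygons(g) == 1

    def test_tree_has_no_faces(self):
        g = graph_from_segments([[[0, 0], [1, 0]], [[1, 0], [2, 0.5]],
                                 [[1, 0], [2, -0.5]]])
        assert ernet.count_polygons(g) == 0

    def test_grid_3x3_has_four_faces(self):
        segs = []
        for i in range(3):
            for j in range(2):
                segs.append([[j, i], [j + 1, i]])
                segs.append([[i, j], [i, j + 1]])
        assert ernet.count_polygons(graph_from_segments(segs)) == 4

    def test_euler_count_matches_enumeration_oracle(self):
        """Euler-formula counts equal brute-force face enumeration on 20
        random planar graphs with <= 30 nodes."""
        checked = 0
        seed = 0
        while checked < 20:
            seed += 1
            g = synthkit.generate_er_graph(
                6, 6, 0.5, 0.2 * (seed % 4), seed=seed)
            if g.n_nodes > 30:
                continue
            assert ernet.count_polygons(g) == count_interior_faces(g)
            checked += 1

    def test_crossing_edges_rejected(self):
        g = graph_from_segments([[[0, 0], [2, 2]], [[0, 2], [2, 0]]])
        with pytest.raises(PlanarityError):
            ernet.count_polygons(g)

    def test_window_clip_opens_boundary_faces(self):
        """A 2x2 block of unit squares clipped to a window covering only
        the lower-left square counts exactly that one polygon."""
        segs = []
        for i in range(3):
            for j in range(2):
                segs.append([[j, i], [j + 1, i]])
                segs.append([[i, j], [i, j + 1]])
        g = graph_from_segments(segs)
        assert ernet.count_polygons(g) == 4
        win = ernet.WindowSpec(area_um2=1.44, position_um=(-0.1, -0.1))
        assert ernet.count_polygons(g, win) == 1

    def test_pruning_never_increases_window_count(self, base_graph):
        windows = [ernet.WindowSpec(100.0, (0.0, 0.0)),
                   ernet.WindowSpec(100.0, (5.0, 5.0))]
        before = [ernet.count_polygons(base_graph, w) for w in windows]
        pruned = ernet.prune_edges(base_graph, 0.3, seed=5)
        after = [ernet.count_polygons(pruned, w) for w in windows]
        assert all(a <= b for a, b in zip(after, before))


class TestScoreAttachments:
    def mk(self, lifetimes):
        return [ernet.AttachmentEvent(0.0, (0, 0), lt,
                                      "successful" if lt >= 5 else "unsuccessful")
                for lt in lifetimes]

    def test_all_persistent_events_score_one(self):
        out = ernet.score_attachments(self.mk([5, 8, 100]), stability_s=5)
        assert out["success_fraction"] == 1.0

    def test_single_transient_event_scores_zero(self):
        out = ernet.score_attachments(self.mk([0.0]), stability_s=5)
        assert out["success_fraction"] == 0.0
        assert out["n_fail"] == 1

    def test_no_events_has_undefined_fraction(self):
        out = ernet.score_attachments([], stability_s=5)
        assert out["n_success"] == 0 and out["success_fraction"] is None

    def test_rates_per_area_per_minute(self):
        out = ernet.score_attachments(self.mk([8, 1, 9, 2]), stability_s=5,
                                      window_area_um2=200.0, duration_s=120.0)
        # 4 events over 2x the standard window and 2 minutes
        assert out["events_per_100um2_per_min"] == pytest.approx(1.0)


class TestDiffusionEngine:
    def test_particle_count_conserved(self, base_graph):
        rec = ernet.simulate_network_diffusion(
            base_graph, 1.0, 500, 0.2, 0.01, 5.0, seed=1,
            record_interval_s=1.0)
        assert rec.positions_um.shape[1] == 500
        assert np.all(rec.fluorescent.sum(axis=1) == 500)

    def test_msd_matches_1d_diffusion_on_isolated_edge(self):
        g = graph_from_segments([[[0, 0], [100, 0]]])
        eng = ernet.NetworkDiffusion(g, 1.0, 10000, 0.0, dt_s=0.01, seed=0)
        eng.p_s[:] = 50.0
        x0 = eng.positions()[:, 0].copy()
        eng.run(100)  # t = 1 s, far from both ends
        msd = np.mean((eng.positions()[:, 0] - x0) ** 2)
        assert msd == pytest.approx(2.0, rel=0.05)

    def test_long_run_occupancy_proportional_to_length(self):
        g = graph_from_segments([[[0, 0], [3, 0]], [[3, 0], [3, 1]],
                                 [[3, 1], [0, 0]]])
        eng = ernet.NetworkDiffusion(g, 0.5, 6000, 0.0, dt_s=0.01, seed=1)
        eng.run(3000)
        counts = np.bincount(eng.p_edge, minlength=3)
        expected = eng.edge_len / eng.edge_len.sum() * eng.n_particles
        assert chisquare(counts, expected).pvalue > 0.01

    def test_dt_violating_step_bound_raises(self, base_graph):
        with pytest.raises(ValueError, match="dt too large"):
            ernet.NetworkDiffusion(base_graph, 5.0, 10, 0.0, dt_s=0.5, seed=0)

    def test_equilibrium_flux_across_midpoints_is_balanced(self):
        """Net signed midpoint crossings vanish at equilibrium."""
        g = graph_from_segments([[[0, 0], [4, 0]], [[4, 0], [4, 3]],
                                 [[4, 3], [0, 0]]])
        eng = ernet.NetworkDiffusion(g, 0.5, 3000, 0.0, dt_s=0.01, seed=3)
        eng.run(500)  # equilibrate
        net = np.zeros(3)
        total = np.zeros(3)
        for _ in range(1500):
            e0 = eng.p_edge.copy()
            side0 = eng.p_s - eng.edge_len[e0] / 2.0
            eng.step()
            same = eng.p_edge == e0
            side1 = eng.p_s - eng.edge_len[eng.p_edge] / 2.0
            crossed = same & (np.sign(side0) != np.sign(side1)) & (side0 != 0)
            for e in range(3):
                sel = crossed & (e0 == e)
                net[e] += np.sum(np.sign(side1[sel]))
                total[e] += sel.sum()
        assert np.all(np.abs(net) <= 4.0 * np.sqrt(total + 1))


class TestSkeletonize:
    def test_blank_image_gives_empty_graph(self):
        g = ernet.skeletonize_to_graph(np.zeros((64, 64)), 100)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_single_tubule_two_endpoints_one_edge(self):
        img = synthkit.rasterize_polylines(
            [np.array([[2.0, 5.0], [14.0, 5.0]])], 1e5, (160, 160), 0.1)
        g = ernet.skeletonize_to_graph(gaussian_filter(img, 1.0), 100)
        assert g.n_nodes == 2 and g.n_edges == 1
        length = next(iter(g.g.edges(data=True)))[2]["length"]
        assert length == pytest.approx(12.0, rel=0.05)

    def test_recovered_polygon_count_close_to_truth(self, base_graph):
        img = synthkit.rasterize_polylines(
            [base_graph.edge_geometry(*e) for e in base_graph.edge_list()],
            1e6, (160, 160), 0.1)
        rec = ernet.skeletonize_to_graph(gaussian_filter(img, 1.0), 100)
        truth = base_graph.interior_faces
        assert abs(rec.interior_faces - truth) <= 0.1 * truth


class TestGraphSerialization:
    def test_json_round_trip_preserves_topology(self, base_graph):
        g2 = ernet.ERGraph.from_json(base_graph.to_json())
        assert g2.n_nodes == base_graph.n_nodes
        assert g2.n_edges == base_graph.n_edges
        assert g2.interior_faces == base_graph.interior_faces

    def test_event_log_jsonl_round_trip(self):
        log = ernet.EventLog([ernet.AttachmentEvent(1.0, (2.0, 3.0), 7.5,
                                                    "successful")],
                             window_area_um2=100.0, duration_s=60.0)
        log2 = ernet.EventLog.from_jsonl(log.to_jsonl(), 100.0, 60.0)
        assert log2.events == log.events
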