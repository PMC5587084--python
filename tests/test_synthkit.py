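"""Generator tests: determinism, conservation laws, planarity, and the
statistical structure of the simulated experiments."""

import numpy as np
import pytest

from ernetics import ernet, inmkinetics, synthkit
from ernetics.core import (BleachSchedule, CellGeometry, ImagingConfig, Roi)

from oracles import segment_crossings


class TestGenerateGraph:
    def test_same_seed_identical(self):
        a = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=1)
        b = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=1)
        assert a.to_json() == b.to_json()

    def test_pruning_reduces_polygon_count(self):
        full = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=1)
        pruned = synthkit.generate_er_graph(10, 10, 0.5, 0.8, seed=1)
        assert ernet.count_polygons(pruned) < ernet.count_polygons(full)

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_planar_by_brute_force(self, seed):
        g = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=seed)
        assert g.n_nodes <= 150
        assert segment_crossings(g) == 0

    def test_degenerate_field_raises(self):
        with pytest.raises(ValueError):
            synthkit.generate_er_graph(0, 10, 0.5, 0.0, seed=1)

    def test_density_too_low_raises(self):
        with pytest.raises(ValueError):
            synthkit.generate_er_graph(2, 2, 0.1, 0.0, seed=1)

    def test_min_edge_bound_holds(self):
        g = synthkit.generate_er_graph(16, 16, 0.5, 0.0, seed=3)
        assert min(d["length"] for *_, d in g.g.edges(data=True)) >= 0.3


class TestRenderCell:
    def test_full_ne_fraction_puts_all_signal_on_ring(self, clean_config,
                                                      geometry, base_graph):
        img, _ = synthkit.render_cell(geometry, base_graph, 1.0, 1e5,
                                      clean_config, seed=1)
        rep = img.channel("gfp")
        # every nonzero pixel lies within one pixel of the nucleus contour
        yy, xx = np.nonzero(rep > 1e-9)
        cx, cy = geometry.nucleus_center_um
        rx, ry = geometry.nucleus_radii_um
        x = (xx + 0.5) * 0.1
        y = (yy + 0.5) * 0.1
        level = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
        assert np.all(np.abs(np.sqrt(level) - 1.0) < 0.1)

    @pytest.mark.parametrize("frac", [0.0, 0.3, 1.0])
    def test_photon_conservation(self, clean_config, geometry, base_graph,
                                 frac):
        img, _ = synthkit.render_cell(geometry, base_graph, frac, 2e5,
                                      clean_config, seed=2)
        assert img.channel("gfp").sum() == pytest.approx(2e5, rel=5e-3)

    def test_graph_outside_boundary_raises(self, clean_config):
        geom = CellGeometry.boxed(8, 8, nucleus_radii_um=(2.0, 1.5))
        big = synthkit.generate_er_graph(16, 16, 0.5, 0.0, seed=1)
        with pytest.raises(ValueError, match="boundary"):
            synthkit.render_cell(geom, big, 0.5, 1e5, clean_config, seed=1)


class TestPhotobleachMovie:
    def test_fully_immobile_stays_at_post_bleach_level(self, clean_config,
                                                       base_graph):
        roi = Roi("circle", (8, 8), (2.5,))
        sch = BleachSchedule.frap(roi, 12.0 - 1e-9, pre_frames=3)
        movie, _ = synthkit.simulate_photobleach_movie(
            base_graph, 1.0, 1.0, sch, 3000, 80.0, clean_config, seed=4)
        mask = roi.mask(160, 160, 0.1)
        means = movie.channel("gfp")[:, mask].mean(axis=1)
        post = means[3:]
        assert np.all(np.abs(post - post[0]) <= 1e-9)  # noiseless: exact

    def test_no_bleach_conserves_total_intensity(self, clean_config,
                                                 base_graph):
        sch = BleachSchedule((), pre_frames=3)
        movie, _ = synthkit.simulate_photobleach_movie(
            base_graph, 1.0, 0.0, sch, 2000, 60.0, clean_config, seed=5)
        totals = movie.channel("gfp").sum(axis=(1, 2))
        assert np.ptp(totals) / totals[0] < 5e-3

    def test_roi_outside_field_raises(self, clean_config, base_graph):
        roi = Roi("circle", (15.5, 8), (2.5,))
        sch = BleachSchedule.frap(roi, 12.0, pre_frames=3)
        with pytest.raises(ValueError, match="outside"):
            synthkit.simulate_photobleach_movie(
                base_graph, 1.0, 0.0, sch, 100, 60.0, clean_config, seed=1)

    def test_more_bleach_iterations_never_brighter(self, clean_config,
                                                   base_graph):
        """Post-bleach spot intensity is non-increasing in the number of
        bleach events applied."""
        roi = Roi("circle", (8, 8), (2.5,))
        mask = roi.mask(160, 160, 0.1)
        finals = []
        for n_events in (1, 3, 8):
            times = 12.0 + 4.0 * np.arange(n_events) - 1e-9
            sch = BleachSchedule(tuple((float(t), roi, 0.0) for t in times),
                                 pre_frames=3)
            movie, _ = synthkit.simulate_photobleach_movie(
                base_graph, 0.5, 0.0, sch, 4000, 60.0, clean_config, seed=6)
            finals.append(movie.channel("gfp")[-1][mask].mean())
        assert finals[0] >= finals[1] >= finals[2]

    def test_connected_network_recovers_to_plateau(self, clean_config,
                                                   base_graph):
        """Full bleach on a well-connected network with no immobile pool:
        full-scale normalized recovery exceeds 0.9 (complete exchange)."""
        from ernetics import photokinetics as pk

        roi = Roi("circle", (8, 8), (2.573,))
        ref = Roi("rectangle", (3, 3), (4, 4))
        sch = BleachSchedule.frap(roi, 12.0 - 1e-9, pre_frames=3)
        movie, _ = synthkit.simulate_photobleach_movie(
            base_graph, 1.0, 0.0, sch, 5000, 300.0, clean_config, seed=8)
        cur = pk.extract_timeseries(movie, {"t": roi, "r": ref})
        curve = pk.normalize_full_scale(cur["t"], cur["r"],
                                        np.zeros(movie.n_frames), 3,
                                        times_s=movie.times_s)
        assert curve.values[-8:].mean() >= 0.9


class TestDynamicsMovie:
    def test_all_events_successful_at_p1(self, base_graph):
        cfg = ImagingConfig(frame_interval_s=1.0, width_px=100, height_px=100)
        g = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=2)
        _, log = synthkit.simulate_dynamics_movie(
            g, 0.03, 1.0, 5.0, 60.0, cfg, seed=3, render=False)
        assert all(e.label == "successful" for e in log)

    def test_event_count_follows_poisson_law(self):
        cfg = ImagingConfig(frame_interval_s=1.0, width_px=100, height_px=100)
        g = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=2)
        rate, T, area = 0.05, 60.0, 100.0
        mean = rate * area * T
        counts = [len(synthkit.simulate_dynamics_movie(
            g, rate, 0.8, 5.0, T, cfg, seed=s, render=False)[1])
            for s in range(10)]
        # each draw within 3 sigma of the Poisson mean
        assert np.all(np.abs(np.array(counts) - mean) <= 3 * np.sqrt(mean))

    def test_success_fraction_within_binomial_ci(self):
        cfg = ImagingConfig(frame_interval_s=1.0, width_px=100, height_px=100)
        g = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=2)
        _, log = synthkit.simulate_dynamics_movie(
            g, 0.08, 0.8, 5.0, 60.0, cfg, seed=9, render=False)
        n = len(log)
        assert n >= 200
        frac = np.mean([e.label == "successful" for e in log])
        half = 2.576 * np.sqrt(0.8 * 0.2 / n)  # 99% CI
        assert abs(frac - 0.8) <= half

    def test_lifetime_consistent_with_label(self):
        cfg = ImagingConfig(frame_interval_s=1.0, width_px=100, height_px=100)
        g = synthkit.generate_er_graph(10, 10, 0.5, 0.0, seed=2)
        _, log = synthkit.simulate_dynamics_movie(
            g, 0.05, 0.5, 5.0, 60.0, cfg, seed=12, render=False)
        for e in log:
            expected = "successful" if e.junction_lifetime_s >= 5.0 \
                else "unsuccessful"
            assert e.label == expected


class TestAccumulationSeries:
    def test_frame_zero_at_baseline_and_plateau_at_long_times(
            self, clean_config, geometry, base_graph):
        model = inmkinetics.DiffusionRetentionModel(
            k_in=np.log(2) / 12.0, baseline_fraction=0.16)
        t = np.array([0.0, 30, 60, 90, 150.0])  # >= 10 half-lives at the end
        _, truth = synthkit.simulate_accumulation_series(
            model, t, geometry, base_graph, clean_config, seed=1,
            total_photons=1e5)
        fr = truth.extra["true_fractions"]
        assert fr[0] == pytest.approx(0.16)
        assert fr[-1] == pytest.approx(1.0, abs=0.01)  # plateau of pure influx

    def test_rejects_decreasing_timepoints(self, clean_config, geometry,
                                           base_graph):
        model = inmkinetics.DiffusionRetentionModel(k_in=0.05)
        with pytest.raises(ValueError):
            synthkit.simulate_accumulation_series(
                model, [0.0, 10.0, 5.0], geometry, base_graph,
                clean_config, seed=1)
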