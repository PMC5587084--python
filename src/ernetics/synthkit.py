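"""Synthetic fluorescence-microscopy generation with known ground truth.

Emulates the imaging experiments the analysis modules quantify: cells
with an elliptical nucleus, an NE ring and a polygonal peripheral ER
network of tunable connectivity; a reporter partitioned between NE and
ER with a known fraction; photobleaching movies driven by particle
diffusion on the network (FRAP and FLIP); tubule attachment dynamics
with a set success probability; and NE-accumulation time series
following the diffusion-retention kinetics.

Every generator takes an explicit seed and returns, alongside the
images, a :class:`~ernetics.core.GroundTruth` record of the true
parameters, so parameter recovery can be tested without external data.
The imaging model is the standard confocal one: expected photon fields
are built by length-weighted deposition of sub-resolution structures
(tubules and the NE ring are ~100 nm wide, far below the PSF), blurred
by a Gaussian PSF, then Poisson shot noise and additive Gaussian read
noise are applied.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box

from .core import (BleachSchedule, CellGeometry, GroundTruth, ImagingConfig,
                   MicroImage, Movie, Roi)
from .ernet import (AttachmentEvent, ERGraph, EventLog, NetworkDiffusion,
                    prune_edges)

__all__ = [
    "generate_er_graph",
    "compose_disjoint",
    "render_cell",
    "simulate_photobleach_movie",
    "simulate_dynamics_movie",
    "simulate_accumulation_series",
    "in_silico_frap",
]


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def generate_er_graph(width_um: float, height_um: float,
                      node_density_per_um2: float, prune_fraction: float,
                      seed: int, min_edge_um: float = 0.3) -> ERGraph:
    """Random polygonal ER network: clipped Voronoi tessellation + pruning.

    A uniform random point set of expected density ``node_density_per_um2``
    is tessellated (Voronoi) and the ridge segments are clipped to the
    field, giving a planar polygonal network — the highly interconnected
    ER of a healthy cell.  ``prune_fraction`` then removes
    ``floor(prune_fraction × E)`` edges uniformly at random, the single
    knob taking the network towards the sparsely connected
    polygons-and-tubules morphology of fusion-impaired cells.

    Edges shorter than ``min_edge_um`` are contracted (their endpoints
    merged at the midpoint) during construction.  This bounds the
    shortest edge from below so the diffusion engine's step-size
    precondition admits a practical time step, without opening
    sub-resolution gaps that an image of the network would not show.
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("field must have positive area")
    if not (0.0 <= prune_fraction <= 1.0):
        raise ValueError("prune_fraction must be in [0, 1]")
    n_pts = int(round(node_density_per_um2 * width_um * height_um))
    if n_pts < 4:
        raise ValueError("node density too low for a tessellation (need >= 4 points)")
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0, width_um, n_pts),
                           rng.uniform(0, height_um, n_pts)])
    vor = Voronoi(pts)
    field = box(0.0, 0.0, width_um, height_um)
    span = max(width_um, height_um) * 4.0
    center = pts.mean(axis=0)

    pieces: list[np.ndarray] = []
    for (p1, p2), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        ridge = np.asarray(ridge)
        if np.all(ridge >= 0):
            a, b = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
        else:
            # semi-infinite ridge: extend from the finite vertex along the
            # outward normal of the generating point pair
            finite = ridge[ridge >= 0][0]
            a = vor.vertices[finite]
            t = pts[p2] - pts[p1]
            t = t / np.linalg.norm(t)
            n = np.array([-t[1], t[0]])
            midpoint = (pts[p1] + pts[p2]) / 2.0
            if np.dot(midpoint - center, n) < 0:
                n = -n
            b = a + n * span
        seg = LineString([a, b]).intersection(field)
        parts = getattr(seg, "geoms", [seg])
        for part in parts:
            if isinstance(part, LineString) and part.length > 1e-9:
                pieces.append(np.asarray(part.coords, dtype=float))

    er = ERGraph.from_segments(pieces)
    _contract_short_edges(er, min_edge_um)
    if er.n_nodes < 3:
        raise ValueError("node density too low for a tessellation")
    if prune_fraction > 0:
        er = prune_edges(er, prune_fraction, seed=seed + 104729)
    return er


def _contract_short_edges(er: ERGraph, min_edge_um: float) -> None:
    """Merge endpoints of straight edges shorter than ``min_edge_um``.

    The merged node sits at the edge midpoint; geometries of incident
    straight edges are rebuilt from the new positions.  Degenerate
    self-loops and duplicated parallels produced by a contraction are
    dropped (they bound zero-area faces)."""
    g = er.g
    changed = True
    while changed:
        changed = False
        for u, v, k, d in sorted(g.edges(keys=True, data=True),
                                 key=lambda e: e[3]["length"]):
            if u == v or d["length"] >= min_edge_um:
                continue
            if not (g.has_node(u) and g.has_node(v) and g.has_edge(u, v, k)):
                continue
            pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
            mid = ((pu[0] + pv[0]) / 2.0, (pu[1] + pv[1]) / 2.0)
            g.remove_edge(u, v, k)
            for _, w, kk, dd in list(g.edges(v, keys=True, data=True)):
                g.remove_edge(v, w, kk)
                g.add_edge(u, u if w == v else w, **dd)
            g.remove_node(v)
            g.nodes[u]["pos"] = mid
            for _, w, kk, dd in g.edges(u, keys=True, data=True):
                pw = g.nodes[w]["pos"]
                dd["length"] = float(np.hypot(pw[0] - mid[0], pw[1] - mid[1]))
            changed = True
    # rebuild straight geometries and lengths from (possibly moved) nodes
    for u, v, k, d in list(g.edges(keys=True, data=True)):
        if u == v:
            g.remove_edge(u, v, k)
            continue
        pu = np.asarray(g.nodes[u]["pos"], dtype=float)
        pv = np.asarray(g.nodes[v]["pos"], dtype=float)
        length = float(np.hypot(*(pv - pu)))
        if length <= 1e-12:
            g.remove_edge(u, v, k)
            continue
        d["geometry"] = np.array([pu, pv])
        d["length"] = length
    # duplicated parallels with identical endpoints bound zero-area faces
    seen: set[tuple[int, int]] = set()
    for u, v, k in list(g.edges(keys=True)):
        pair = (min(u, v), max(u, v))
        if pair in seen:
            g.remove_edge(u, v, k)
        else:
            seen.add(pair)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])


def compose_disjoint(a: ERGraph, b: ERGraph,
                     offset_um: tuple[float, float] = (0.0, 0.0)) -> ERGraph:
    """Disjoint union of two networks, translating ``b`` by ``offset_um``.

    Useful for constructing fields with physically disconnected ER
    islands (e.g. a fragmented component a FLIP protocol cannot drain).
    """
    segs = [a.edge_geometry(*e) for e in a.edge_list()]
    off = np.asarray(offset_um, dtype=float)
    segs += [b.edge_geometry(*e) + off for e in b.edge_list()]
    return ERGraph.from_segments(segs)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _deposit(expected: np.ndarray, xy_um: np.ndarray, weights: np.ndarray,
             px_um: float) -> None:
    """Accumulate point weights into pixel bins (clamped at the border)."""
    H, W = expected.shape
    col = np.clip((xy_um[:, 0] / px_um).astype(np.int64), 0, W - 1)
    row = np.clip((xy_um[:, 1] / px_um).astype(np.int64), 0, H - 1)
    np.add.at(expected, (row, col), weights)


def rasterize_polylines(polylines: list[np.ndarray], total_photons: float,
                        shape: tuple[int, int], px_um: float,
                        samples_per_px: float = 5.0) -> np.ndarray:
    """Expected-photon field with ``total_photons`` spread uniformly per
    unit length along the given polylines (photon-conserving)."""
    expected = np.zeros(shape, dtype=float)
    lengths = [float(np.sum(np.hypot(*np.diff(p, axis=0).T))) for p in polylines]
    total_len = sum(lengths)
    if total_len == 0 or total_photons == 0:
        return expected
    spacing = px_um / samples_per_px
    for pts, plen in zip(polylines, lengths):
        if plen <= 0:
            continue
        seg_len = np.hypot(*np.diff(pts, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        n = max(int(np.ceil(plen / spacing)), 2)
        s = (np.arange(n) + 0.5) * plen / n
        xs = np.interp(s, cum, pts[:, 0])
        ys = np.interp(s, cum, pts[:, 1])
        w = np.full(n, total_photons * plen / total_len / n)
        _deposit(expected, np.column_stack([xs, ys]), w, px_um)
    return expected


def rasterize_ellipse_ring(center_um: tuple[float, float],
                           radii_um: tuple[float, float],
                           total_photons: float, shape: tuple[int, int],
                           px_um: float, samples_per_px: float = 5.0
                           ) -> np.ndarray:
    """Expected-photon field with photons uniform per unit arc length on an
    ellipse perimeter (the NE ring)."""
    expected = np.zeros(shape, dtype=float)
    if total_photons == 0:
        return expected
    rx, ry = radii_um
    # dense parameter sampling weighted by local speed ⇒ uniform per arc
    n = max(int(np.ceil(2 * np.pi * max(rx, ry) / (px_um / samples_per_px))), 64)
    t = (np.arange(n) + 0.5) * 2 * np.pi / n
    xs = center_um[0] + rx * np.cos(t)
    ys = center_um[1] + ry * np.sin(t)
    speed = np.hypot(rx * np.sin(t), ry * np.cos(t))
    w = total_photons * speed / speed.sum()
    _deposit(expected, np.column_stack([xs, ys]), w, px_um)
    return expected


def apply_imaging(expected: np.ndarray, config: ImagingConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """PSF blur, then Poisson shot noise and Gaussian read noise."""
    img = expected
    if config.psf_sigma_nm > 0:
        img = gaussian_filter(img, config.psf_sigma_nm / config.pixel_size_nm,
                              mode="constant")
    img = img * config.photon_scale
    if config.shot_noise:
        img = rng.poisson(img).astype(float)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, img.shape)
    return img


# ---------------------------------------------------------------------------
# still cells
# ---------------------------------------------------------------------------

def render_cell(geometry: CellGeometry, graph: ERGraph,
                ne_fraction_true: float, total_photons: float,
                config: ImagingConfig, seed: int,
                nucleus_photons_per_px: float = 50.0
                ) -> tuple[MicroImage, GroundTruth]:
    """Render a two-channel cell image (nucleus + reporter).

    Channel ``dapi`` is the filled nucleus ellipse; channel ``gfp`` is the
    reporter with expected intensity ``ne_fraction_true × total_photons``
    uniform along the NE ring and the rest uniform per unit length along
    the ER tubules (tubule pieces inside the nucleus are clipped away:
    the peripheral ER surrounds the nucleus).  PSF blur and noise follow
    ``config``.
    """
    if not (0.0 <= ne_fraction_true <= 1.0):
        raise ValueError("ne_fraction_true must be in [0, 1]")
    from shapely.geometry import LineString, Polygon

    cell_poly = Polygon(geometry.cell_boundary_um).buffer(1e-6)
    nucleus = geometry.nucleus_polygon()
    polylines: list[np.ndarray] = []
    for e in graph.edge_list():
        geom = graph.edge_geometry(*e)
        line = LineString(geom)
        if not cell_poly.contains(line):
            raise ValueError("ER graph extends outside the cell boundary")
        clipped = line.difference(nucleus)
        for part in getattr(clipped, "geoms", [clipped]):
            if isinstance(part, LineString) and part.length > 0:
                polylines.append(np.asarray(part.coords, dtype=float))

    shape = (config.height_px, config.width_px)
    px = config.pixel_size_um
    rng = np.random.default_rng(seed)
    er_expected = rasterize_polylines(
        polylines, (1.0 - ne_fraction_true) * total_photons, shape, px)
    ne_expected = rasterize_ellipse_ring(
        geometry.nucleus_center_um, geometry.nucleus_radii_um,
        ne_fraction_true * total_photons, shape, px)
    reporter = apply_imaging(er_expected + ne_expected, config, rng)
    nucleus_expected = geometry.nucleus_mask(*shape, px) * nucleus_photons_per_px
    dapi = apply_imaging(nucleus_expected, config, rng)

    image = MicroImage(np.stack([dapi, reporter]), ("dapi", "gfp"),
                       config.pixel_size_nm)
    truth = GroundTruth(seed=seed, ne_fraction_true=ne_fraction_true,
                        extra={"total_photons": total_photons})
    return image, truth


# ---------------------------------------------------------------------------
# photobleaching movies (FRAP / FLIP)
# ---------------------------------------------------------------------------

def _render_particles(xy: np.ndarray, config: ImagingConfig,
                      photons_per_particle: float,
                      rng: np.random.Generator) -> np.ndarray:
    shape = (config.height_px, config.width_px)
    expected = np.zeros(shape, dtype=float)
    if xy.shape[0]:
        _deposit(expected, xy,
                 np.full(xy.shape[0], photons_per_particle),
                 config.pixel_size_um)
    return apply_imaging(expected, config, rng)


def simulate_photobleach_movie(graph: ERGraph, diffusion_um2_s: float,
                               immobile_fraction: float,
                               schedule: BleachSchedule, n_particles: int,
                               duration_s: float, config: ImagingConfig,
                               seed: int,
                               photons_per_particle: float = 20.0
                               ) -> tuple[Movie, GroundTruth]:
    """Photobleaching movie driven by particle diffusion on the network.

    Covers both FRAP (single bleach event) and FLIP (repeated events)
    through the schedule.  Frames are rendered from the fluorescent
    particle positions at every frame interval; at each bleach event,
    particles inside the event ROI are switched dark with the scheduled
    depletion.  A fraction of particles assigned at initialisation never
    moves, producing a recovery plateau below 1.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    w_um, h_um = config.field_um
    for t, roi, _ in schedule.events:
        x0, y0, x1, y1 = roi.bounds_um()
        if x0 < 0 or y0 < 0 or x1 > w_um or y1 > h_um:
            raise ValueError("bleach ROI lies outside the field")
        if t > duration_s:
            raise ValueError("duration does not cover the bleach schedule")

    interval = config.frame_interval_s
    dt = interval
    if diffusion_um2_s > 0:
        # largest dt obeying sqrt(2 D dt) <= L_min/2, with 10% margin
        min_edge = min(d["length"] for *_, d in graph.g.edges(data=True))
        dt_max = 0.9 * (min_edge / 2.0) ** 2 / (2.0 * diffusion_um2_s)
        dt = min(interval, dt_max)
    steps_per_frame = max(int(np.ceil(interval / dt)), 1)
    dt = interval / steps_per_frame

    eng = NetworkDiffusion(graph, diffusion_um2_s, n_particles,
                           immobile_fraction, dt_s=dt, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_frames = int(np.floor(duration_s / interval)) + 1
    events = list(schedule.events)
    frames = []
    next_event = 0
    for f in range(n_frames):
        t_frame = f * interval
        if f > 0:
            for _ in range(steps_per_frame):
                eng.step()
                while (next_event < len(events)
                       and events[next_event][0] <= eng.time_s):
                    _, roi, depletion = events[next_event]
                    eng.bleach(roi, survival_prob=depletion)
                    next_event += 1
        else:
            while next_event < len(events) and events[next_event][0] <= 0.0:
                _, roi, depletion = events[next_event]
                eng.bleach(roi, survival_prob=depletion)
                next_event += 1
        xy = eng.positions()[eng.fluorescent]
        frames.append(_render_particles(xy, config, photons_per_particle, rng))

    movie = Movie(np.asarray(frames)[:, None], ("gfp",),
                  config.pixel_size_nm, interval)
    truth = GroundTruth(seed=seed, diffusion_um2_s=diffusion_um2_s,
                        immobile_fraction=immobile_fraction,
                        extra={"n_particles": n_particles,
                               "photons_per_particle": photons_per_particle,
                               "n_bleach_events": len(events)})
    return movie, truth


def in_silico_frap(graph: ERGraph, protocol: dict, seed: int):
    """Run a FRAP protocol on a network and fit the recovery.

    ``protocol`` keys: ``roi``, ``reference_roi`` (:class:`Roi`),
    ``diffusion_um2_s``, ``immobile_fraction``, ``n_particles``,
    ``duration_s``, ``config``; optional ``pre_frames`` (default 3).
    Returns the :class:`~ernetics.photokinetics.FrapResults`.
    """
    from . import photokinetics

    config: ImagingConfig = protocol["config"]
    pre_frames = protocol.get("pre_frames", 3)
    roi: Roi = protocol["roi"]
    # bleach immediately before the first post-bleach frame, so that frame
    # images the depleted state rather than 2 s of refill
    bleach_time = pre_frames * config.frame_interval_s - 1e-9
    schedule = BleachSchedule.frap(roi, bleach_time, pre_frames=pre_frames)
    movie, _ = simulate_photobleach_movie(
        graph, protocol["diffusion_um2_s"], protocol["immobile_fraction"],
        schedule, protocol["n_particles"], protocol["duration_s"], config,
        seed=seed)
    rois = {"target": roi, "reference": protocol["reference_roi"]}
    curves = photokinetics.extract_timeseries(movie, rois)
    background = np.zeros_like(curves["target"])
    curve = photokinetics.normalize_full_scale(
        curves["target"], curves["reference"], background, pre_frames,
        times_s=movie.times_s)
    return photokinetics.fit_double_exponential(curve)


def in_silico_flip(graph: ERGraph, protocol: dict, seed: int):
    """Run a FLIP protocol on a network and compute the loss metrics.

    ``protocol`` keys: ``spot`` (circular :class:`Roi`), ``distant_roi``,
    ``diffusion_um2_s``, ``n_particles``, ``config``; optional
    ``duration_s`` (default 720, the 12-min course), ``bleach_interval_s``
    (default 4.5) and ``pre_frames`` (default 2).  The donut is the ring
    of one spot-radius width surrounding the spot.  Returns
    ``(FlipResult, curves dict)``.
    """
    from . import photokinetics

    config: ImagingConfig = protocol["config"]
    spot: Roi = protocol["spot"]
    duration = protocol.get("duration_s", 720.0)
    pre = protocol.get("pre_frames", 2)
    r = spot.dims_um[0]
    donut = Roi("annulus", spot.center_um, (r, 2 * r))
    schedule = BleachSchedule.flip(
        spot, start_s=pre * config.frame_interval_s - 1e-9,
        interval_s=protocol.get("bleach_interval_s", 4.5),
        duration_s=duration, pre_frames=pre)
    movie, _ = simulate_photobleach_movie(
        graph, protocol["diffusion_um2_s"],
        protocol.get("immobile_fraction", 0.0), schedule,
        protocol["n_particles"], duration, config, seed=seed)
    raw = photokinetics.extract_timeseries(
        movie, {"spot": spot, "donut": donut,
                "distant": protocol["distant_roi"]})
    norm = {k: v / v[:pre].mean() for k, v in raw.items()}
    result = photokinetics.flip_metrics(norm, movie.times_s, pre)
    return result, norm


# ---------------------------------------------------------------------------
# ER dynamics movies
# ---------------------------------------------------------------------------

def simulate_dynamics_movie(graph: ERGraph, growth_rate_per_um2_s: float,
                            attach_success_p: float, stability_s: float,
                            duration_s: float, config: ImagingConfig,
                            seed: int, render: bool = True,
                            photons_total: float = 2e5
                            ) -> tuple[Movie | None, EventLog]:
    """Tubule-growth/attachment dynamics with a set success probability.

    Growth events arise as a spatial Poisson process of intensity
    ``growth_rate_per_um2_s`` over the field.  Each emerging tubule
    reaches an opposing membrane and with probability ``attach_success_p``
    forms a junction persisting at least ``stability_s`` (successful);
    otherwise it detaches earlier (unsuccessful).  The event log records
    every event's time, position, lifetime and true label.
    """
    if growth_rate_per_um2_s <= 0 or stability_s <= 0:
        raise ValueError("rates and stability must be > 0")
    if duration_s < stability_s:
        raise ValueError("duration must cover at least one stability window")
    if not (0.0 <= attach_success_p <= 1.0):
        raise ValueError("attach_success_p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    w_um, h_um = config.field_um
    area = w_um * h_um
    n_events = rng.poisson(growth_rate_per_um2_s * area * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n_events))
    x = rng.uniform(0.0, w_um, n_events)
    y = rng.uniform(0.0, h_um, n_events)
    success = rng.random(n_events) < attach_success_p
    # successful junctions persist beyond the stability threshold;
    # unsuccessful ones detach well before it
    lifetime = np.where(
        success,
        stability_s + rng.exponential(3.0 * stability_s, n_events),
        rng.uniform(0.0, 0.8 * stability_s, n_events))
    events = [AttachmentEvent(float(ti), (float(xi), float(yi)), float(li),
                              "successful" if si else "unsuccessful")
              for ti, xi, yi, li, si in zip(t, x, y, lifetime, success)]
    log = EventLog(events, window_area_um2=area, duration_s=duration_s)

    movie = None
    if render:
        shape = (config.height_px, config.width_px)
        px = config.pixel_size_um
        base_lines = [graph.edge_geometry(*e) for e in graph.edge_list()]
        base = rasterize_polylines(base_lines, photons_total, shape, px)
        angle = rng.uniform(0, 2 * np.pi, n_events)
        tubule_len = rng.uniform(0.5, 1.5, n_events)
        n_frames = int(np.floor(duration_s / config.frame_interval_s)) + 1
        frames = []
        for f in range(n_frames):
            tf = f * config.frame_interval_s
            expected = base.copy()
            active = (t <= tf) & (tf < t + lifetime)
            lines = []
            for i in np.nonzero(active)[0]:
                p0 = np.array([x[i], y[i]])
                p1 = p0 + tubule_len[i] * np.array([np.cos(angle[i]),
                                                   np.sin(angle[i])])
                p1 = np.clip(p1, 0, [w_um, h_um])
                lines.append(np.array([p0, p1]))
            if lines:
                per_tubule = photons_total * 0.01 * len(lines)
                expected = expected + rasterize_polylines(
                    lines, per_tubule, shape, px)
            frames.append(apply_imaging(expected, config, rng))
        movie = Movie(np.asarray(frames)[:, None], ("gfp",),
                      config.pixel_size_nm, config.frame_interval_s)
    return movie, log


# ---------------------------------------------------------------------------
# NE accumulation series
# ---------------------------------------------------------------------------

def simulate_accumulation_series(model, timepoints_min, geometry: CellGeometry,
                                 graph: ERGraph, config: ImagingConfig,
                                 seed: int, total_photons: float = 4e5
                                 ) -> tuple[Movie, GroundTruth]:
    """Render one two-channel frame per timepoint with the NE fraction
    following the diffusion-retention kinetics (frame 0 at the model's
    baseline fraction)."""
    timepoints_min = np.asarray(timepoints_min, dtype=float)
    if timepoints_min[0] != 0 or np.any(np.diff(timepoints_min) < 0):
        raise ValueError("timepoints must be non-decreasing and start at 0")
    curve = model.simulate(timepoints_min)
    frames = []
    for i, frac in enumerate(curve.values):
        img, _ = render_cell(geometry, graph, float(frac), total_photons,
                             config, seed=seed + 7919 * i)
        frames.append(img.data)
    interval_s = (float(timepoints_min[1] - timepoints_min[0]) * 60.0
                  if len(timepoints_min) > 1 else 1.0)
    movie = Movie(np.asarray(frames), ("dapi", "gfp"), config.pixel_size_nm,
                  interval_s, times_s=timepoints_min * 60.0)
    truth = GroundTruth(seed=seed, kinetic_params=model.to_dict(),
                        extra={"true_fractions": [float(v) for v in curve.values],
                               "timepoints_min": timepoints_min.tolist()})
    return movie, truth
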