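"""ER-network structure and dynamics analysis.

The peripheral ER is modelled as a planar spatial graph: junction points
(three-way tubule junctions, free tubule tips) are nodes with 2-D
coordinates in μm, tubules are edges.  Connectivity of the network is
summarised by the number of closed polygons in a fixed-area window, the
field's standard readout; on the dynamics side, tubule-attachment events
are scored successful/unsuccessful against a junction-stability threshold,
and fluorescent-protein mobility is probed by simulating Brownian
particles diffusing along the tubule graph (in-silico FRAP).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, box

from .core import PlanarityError, Roi

__all__ = [
    "ERGraph",
    "WindowSpec",
    "AttachmentEvent",
    "EventLog",
    "find_crossings",
    "count_polygons",
    "clip_to_window",
    "prune_edges",
    "score_attachments",
    "NetworkDiffusion",
    "simulate_network_diffusion",
    "skeletonize_to_graph",
    "connectivity_mobility_curve",
]

_COORD_DECIMALS = 9  # node-merge tolerance when keying nodes by coordinate


class ERGraph:
    """Planar spatial graph of the ER (μm coordinates).

    Backed by a :class:`networkx.MultiGraph` whose nodes carry a ``pos``
    attribute ``(x_um, y_um)`` and whose edges carry ``length`` (μm) and
    ``geometry`` (an ``(k, 2)`` polyline; straight edges have ``k = 2``).
    A multigraph is used because skeleton-derived networks legitimately
    contain parallel arcs (two tubule paths between the same pair of
    junctions bound a polygon) and loops.
    """

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.g = graph if graph is not None else nx.MultiGraph()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_segments(cls, segments: Iterable[np.ndarray]) -> "ERGraph":
        """Build a graph from polyline segments, merging coincident endpoints."""
        er = cls()
        key_to_node: dict[tuple, int] = {}

        def node_for(pt: np.ndarray) -> int:
            key = (round(float(pt[0]), _COORD_DECIMALS),
                   round(float(pt[1]), _COORD_DECIMALS))
            if key not in key_to_node:
                nid = len(key_to_node)
                key_to_node[key] = nid
                er.g.add_node(nid, pos=(float(pt[0]), float(pt[1])))
            return key_to_node[key]

        for seg in segments:
            seg = np.asarray(seg, dtype=float)
            length = float(np.sum(np.hypot(*np.diff(seg, axis=0).T)))
            if length <= 0:
                continue
            u = node_for(seg[0])
            v = node_for(seg[-1])
            er.g.add_edge(u, v, length=length, geometry=seg)
        return er

    # -- bookkeeping -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.g) if self.n_nodes else 0

    @property
    def interior_faces(self) -> int:
        """Closed-polygon count by Euler's relation for a planar graph.

        For a planar graph with ``V`` vertices, ``E`` edges and ``C``
        connected components, ``V − E + F = 1 + C`` where ``F`` counts all
        faces including the unbounded one, so interior faces number
        ``E − V + C``.
        """
        return self.n_edges - self.n_nodes + self.n_components

    def positions(self) -> dict[int, tuple[float, float]]:
        return dict(self.g.nodes(data="pos"))

    def edge_list(self) -> list[tuple[int, int, int]]:
        return list(self.g.edges(keys=True))

    def edge_geometry(self, u: int, v: int, k: int) -> np.ndarray:
        geom = self.g.edges[u, v, k].get("geometry")
        if geom is None:
            pu, pv = self.g.nodes[u]["pos"], self.g.nodes[v]["pos"]
            geom = np.array([pu, pv], dtype=float)
        return np.asarray(geom, dtype=float)

    def total_length(self) -> float:
        return float(sum(d["length"] for *_, d in self.g.edges(data=True)))

    def copy(self) -> "ERGraph":
        return ERGraph(self.g.copy())

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.array([p for _, p in self.g.nodes(data="pos")], dtype=float)
        return (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        nodes = [[int(n), *map(float, p)] for n, p in self.g.nodes(data="pos")]
        edges = [[int(u), int(v)] for u, v, _ in self.g.edges(keys=True)]
        return json.dumps({"nodes": nodes, "edges": edges})

    @classmethod
    def from_json(cls, text: str) -> "ERGraph":
        d = json.loads(text)
        g = nx.MultiGraph()
        for n, x, y in d["nodes"]:
            g.add_node(int(n), pos=(float(x), float(y)))
        for u, v in d["edges"]:
            pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
            length = float(np.hypot(pv[0] - pu[0], pv[1] - pu[1]))
            g.add_edge(int(u), int(v), length=length,
                       geometry=np.array([pu, pv], dtype=float))
        return cls(g)


@dataclass(frozen=True)
class WindowSpec:
    """Square analysis window; ``position_um`` anchors the top-left corner.

    The default 100 μm² matches the standard fixed-area window used to
    count polygons and attachment events in the peripheral ER.
    """

    area_um2: float = 100.0
    position_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("window area must be > 0")

    @property
    def side_um(self) -> float:
        return float(np.sqrt(self.area_um2))

    def polygon(self):
        x0, y0 = self.position_um
        return box(x0, y0, x0 + self.side_um, y0 + self.side_um)


@dataclass(frozen=True)
class AttachmentEvent:
    """One tubule-attachment event from a dynamics movie or event log."""

    t_start_s: float
    position_um: tuple[float, float]
    junction_lifetime_s: float
    label: str  # "successful" | "unsuccessful"

    def __post_init__(self) -> None:
        if self.junction_lifetime_s < 0:
            raise ValueError("junction lifetime must be >= 0")
        if self.label not in ("successful", "unsuccessful"):
            raise ValueError("label must be successful|unsuccessful")


@dataclass
class EventLog:
    """Attachment events plus the observation context they came from."""

    events: list[AttachmentEvent] = field(default_factory=list)
    window_area_um2: float | None = None
    duration_s: float | None = None

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def to_jsonl(self) -> str:
        lines = []
        for e in self.events:
            lines.append(json.dumps({
                "t": e.t_start_s, "x_um": e.position_um[0],
                "y_um": e.position_um[1],
                "lifetime_s": e.junction_lifetime_s, "label": e.label,
            }))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str, window_area_um2: float | None = None,
                   duration_s: float | None = None) -> "EventLog":
        events = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(AttachmentEvent(d["t"], (d["x_um"], d["y_um"]),
                                          d["lifetime_s"], d["label"]))
        return cls(events, window_area_um2, duration_s)


# ---------------------------------------------------------------------------
# planarity
# ---------------------------------------------------------------------------

def find_crossings(graph: ERGraph) -> list[tuple]:
    """Brute-force pairwise segment-intersection check.

    Returns the list of edge pairs whose geometries intersect anywhere
    other than at a shared node.  Empty list ⇔ the embedding is planar.
    """
    edges = graph.edge_list()
    geoms = [LineString(graph.edge_geometry(*e)) for e in edges]
    bboxes = np.array([g.bounds for g in geoms]) if geoms else np.empty((0, 4))
    crossings = []
    for i, j in itertools.combinations(range(len(edges)), 2):
        ui, vi, _ = edges[i]
        uj, vj, _ = edges[j]
        if {ui, vi} & {uj, vj}:
            continue  # adjacent edges meet at their shared node by design
        if (bboxes[i, 2] < bboxes[j, 0] or bboxes[j, 2] < bboxes[i, 0]
                or bboxes[i, 3] < bboxes[j, 1] or bboxes[j, 3] < bboxes[i, 1]):
            continue
        if geoms[i].intersects(geoms[j]):
            crossings.append((edges[i], edges[j]))
    return crossings


# ---------------------------------------------------------------------------
# polygon counting
# ---------------------------------------------------------------------------

def clip_to_window(graph: ERGraph, window: WindowSpec) -> ERGraph:
    """Restrict a graph to a window, cutting edges at the boundary.

    Cut points become degree-1 nodes, so polygons only partially inside
    the window are opened and not counted — matching how a human scorer
    counts only polygons fully visible in the window.
    """
    poly = window.polygon()
    pieces: list[np.ndarray] = []
    for e in graph.edge_list():
        geom = LineString(graph.edge_geometry(*e))
        inter = geom.intersection(poly)
        if inter.is_empty:
            continue
        parts = getattr(inter, "geoms", [inter])
        for part in parts:
            if isinstance(part, LineString) and part.length > 0:
                pieces.append(np.asarray(part.coords, dtype=float))
    return ERGraph.from_segments(pieces)


def count_polygons(graph: ERGraph, window: WindowSpec | None = None) -> int:
    """Number of closed polygons (interior faces), optionally within a window.

    Validates planarity by brute force and applies Euler's relation
    ``faces = E − V + C``.
    """
    g = clip_to_window(graph, window) if window is not None else graph
    crossings = find_crossings(g)
    if crossings:
        raise PlanarityError(f"graph has {len(crossings)} crossing edge pair(s)")
    return max(g.interior_faces, 0)


def prune_edges(graph: ERGraph, prune_fraction: float, seed: int) -> ERGraph:
    """Remove ``floor(prune_fraction × E)`` edges uniformly at random.

    Isolated nodes left behind are dropped.  The result is a subgraph of
    the input, so pruning can never create new polygons.
    """
    if not (0.0 <= prune_fraction <= 1.0):
        raise ValueError("prune_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = graph.edge_list()
    n_remove = int(np.floor(prune_fraction * len(edges)))
    g = graph.g.copy()
    if n_remove:
        idx = rng.choice(len(edges), size=n_remove, replace=False)
        for i in idx:
            g.remove_edge(*edges[i])
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return ERGraph(g)


# ---------------------------------------------------------------------------
# attachment scoring
# ---------------------------------------------------------------------------

def score_attachments(events: EventLog | Sequence[AttachmentEvent],
                      stability_s: float = 5.0,
                      window_area_um2: float | None = None,
                      duration_s: float | None = None) -> dict:
    """Score tubule-attachment events against a junction-stability threshold.

    An event counts as successful iff its junction persisted for at least
    ``stability_s``.  Returns counts, the success fraction (``None`` when
    there are no events), and — when the observation window area and
    duration are known — event rates per 100 μm² per minute.
    """
    if isinstance(events, EventLog):
        window_area_um2 = window_area_um2 or events.window_area_um2
        duration_s = duration_s or events.duration_s
        events = events.events
    n_success = sum(1 for e in events if e.junction_lifetime_s >= stability_s)
    n_fail = len(events) - n_success
    total = n_success + n_fail
    out = {
        "n_success": n_success,
        "n_fail": n_fail,
        "success_fraction": (n_success / total) if total else None,
    }
    if window_area_um2 and duration_s:
        per = (window_area_um2 / 100.0) * (duration_s / 60.0)
        out["events_per_100um2_per_min"] = total / per
        out["success_per_100um2_per_min"] = n_success / per
    return out


# ---------------------------------------------------------------------------
# diffusion on the network
# ---------------------------------------------------------------------------

class NetworkDiffusion:
    """Brownian particles diffusing along the edges of a spatial graph.

    Mobile particles take 1-D Gaussian steps of sd ``sqrt(2 D dt)`` along
    their current edge; on reaching a node the continuing edge is drawn
    uniformly among the node's incident edges (the arrival edge included,
    which reflects at degree-1 tips).  A fixed subset of particles is
    immobile from initialisation; any particle can additionally be
    switched dark by a bleach event.  Particle number is conserved.

    The step-size precondition ``sqrt(2 D dt) ≤ L_min / 2`` (half the
    shortest edge) keeps multi-node hops within one step rare; the rare
    overshoot past a second node is clamped to the far end of the new
    edge.
    """

    def __init__(self, graph: ERGraph, diffusion_um2_s: float,
                 n_particles: int, immobile_fraction: float = 0.0,
                 dt_s: float = 0.01, seed: int = 0):
        if n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not (0.0 <= immobile_fraction <= 1.0):
            raise ValueError("immobile_fraction must be in [0, 1]")
        if diffusion_um2_s < 0:
            raise ValueError("diffusion_um2_s must be >= 0")
        if graph.n_edges == 0:
            raise ValueError("graph has no edges")
        self.graph = graph
        self.D = float(diffusion_um2_s)
        self.dt = float(dt_s)
        self.rng = np.random.default_rng(seed)

        pos = graph.positions()
        node_ids = list(graph.g.nodes)
        self._nidx = {n: i for i, n in enumerate(node_ids)}
        self.node_xy = np.array([pos[n] for n in node_ids], dtype=float)

        edges = graph.edge_list()
        self.edge_u = np.array([self._nidx[u] for u, _, _ in edges])
        self.edge_v = np.array([self._nidx[v] for _, v, _ in edges])
        p0 = self.node_xy[self.edge_u]
        p1 = self.node_xy[self.edge_v]
        d = p1 - p0
        self.edge_len = np.hypot(d[:, 0], d[:, 1])
        if np.any(self.edge_len <= 0):
            raise ValueError("graph contains zero-length edges")
        self.edge_dir = d / self.edge_len[:, None]
        self.edge_p0 = p0

        self.step_sd = np.sqrt(2.0 * self.D * self.dt)
        self.min_edge = float(self.edge_len.min())
        if self.D > 0 and self.step_sd > self.min_edge / 2.0:
            raise ValueError(
                f"dt too large: step sd {self.step_sd:.4g} μm exceeds half the "
                f"shortest edge ({self.min_edge / 2.0:.4g} μm)")

        # incidence lists (flat ragged arrays) for junction routing
        n_nodes = len(node_ids)
        inc: list[list[tuple[int, bool]]] = [[] for _ in range(n_nodes)]
        for ei in range(len(edges)):
            inc[self.edge_u[ei]].append((ei, True))
            inc[self.edge_v[ei]].append((ei, False))
        self.inc_off = np.zeros(n_nodes + 1, dtype=np.int64)
        flat_e, flat_s = [], []
        for i, lst in enumerate(inc):
            self.inc_off[i + 1] = self.inc_off[i] + len(lst)
            for ei, is_start in lst:
                flat_e.append(ei)
                flat_s.append(is_start)
        self.inc_edge = np.array(flat_e, dtype=np.int64)
        self.inc_isstart = np.array(flat_s, dtype=bool)
        self.inc_deg = np.diff(self.inc_off)

        # initial positions: uniform per unit tubule length
        w = self.edge_len / self.edge_len.sum()
        self.p_edge = self.rng.choice(len(edges), size=n_particles, p=w)
        self.p_s = self.rng.uniform(0.0, self.edge_len[self.p_edge])
        n_imm = int(round(immobile_fraction * n_particles))
        order = self.rng.permutation(n_particles)
        self.mobile = np.ones(n_particles, dtype=bool)
        self.mobile[order[:n_imm]] = False
        self.fluorescent = np.ones(n_particles, dtype=bool)
        self.time_s = 0.0

    @property
    def n_particles(self) -> int:
        return self.p_edge.shape[0]

    def step(self) -> None:
        """Advance all particles by one time step ``dt``."""
        if self.D > 0:
            mob = self.mobile
            s = self.p_s
            s[mob] = s[mob] + self.rng.normal(0.0, self.step_sd, mob.sum())
            L = self.edge_len[self.p_edge]
            over = s > L
            under = s < 0.0
            trans = over | under
            if np.any(trans):
                ti = np.nonzero(trans)[0]
                e = self.p_edge[ti]
                at_end = over[ti]
                node = np.where(at_end, self.edge_v[e], self.edge_u[e])
                excess = np.where(at_end, s[ti] - self.edge_len[e], -s[ti])
                deg = self.inc_deg[node]
                pick = self.inc_off[node] + (
                    self.rng.random(ti.size) * deg).astype(np.int64)
                new_e = self.inc_edge[pick]
                from_start = self.inc_isstart[pick]
                new_len = self.edge_len[new_e]
                s_new = np.where(from_start, excess, new_len - excess)
                np.clip(s_new, 0.0, new_len, out=s_new)
                self.p_edge[ti] = new_e
                s[ti] = s_new
        self.time_s += self.dt

    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self.step()

    def positions(self) -> np.ndarray:
        """Current (n_particles, 2) μm coordinates."""
        return (self.edge_p0[self.p_edge]
                + self.edge_dir[self.p_edge] * self.p_s[:, None])

    def bleach(self, roi: Roi, survival_prob: float = 0.0) -> int:
        """Switch fluorescent particles inside ``roi`` dark.

        Each stays fluorescent with probability ``survival_prob``
        (0 = complete bleach).  Returns the number bleached.
        """
        xy = self.positions()
        inside = roi.contains(xy[:, 0], xy[:, 1]) & self.fluorescent
        if survival_prob > 0:
            keep = self.rng.random(self.n_particles) < survival_prob
            inside &= ~keep
        self.fluorescent[inside] = False
        return int(inside.sum())

    def roi_count(self, roi: Roi, fluorescent_only: bool = True) -> int:
        xy = self.positions()
        inside = roi.contains(xy[:, 0], xy[:, 1])
        if fluorescent_only:
            inside &= self.fluorescent
        return int(inside.sum())


@dataclass
class TrajectoryRecord:
    """Recorded particle positions: ``positions_um`` is (n_times, n, 2)."""

    times_s: np.ndarray
    positions_um: np.ndarray
    fluorescent: np.ndarray  # (n_times, n) bool


def simulate_network_diffusion(graph: ERGraph, diffusion_um2_s: float,
                               n_particles: int, immobile_fraction: float,
                               dt_s: float, duration_s: float, seed: int,
                               record_interval_s: float | None = None,
                               ) -> TrajectoryRecord:
    """Run the diffusion engine and record trajectories at fixed intervals."""
    eng = NetworkDiffusion(graph, diffusion_um2_s, n_particles,
                           immobile_fraction, dt_s, seed)
    if record_interval_s is None:
        record_interval_s = duration_s / 10.0
    steps_per_rec = max(int(round(record_interval_s / dt_s)), 1)
    n_total = int(round(duration_s / dt_s))
    times, posns, fluo = [0.0], [eng.positions().copy()], [eng.fluorescent.copy()]
    done = 0
    while done < n_total:
        n = min(steps_per_rec, n_total - done)
        eng.run(n)
        done += n
        times.append(eng.time_s)
        posns.append(eng.positions().copy())
        fluo.append(eng.fluorescent.copy())
    return TrajectoryRecord(np.array(times), np.array(posns), np.array(fluo))


# ---------------------------------------------------------------------------
# image → graph
# ---------------------------------------------------------------------------

def skeletonize_to_graph(er_image: np.ndarray, pixel_size_nm: float,
                         threshold: float | None = None,
                         spur_px: int = 3,
                         junction_merge_px: float = 4.0) -> ERGraph:
    """Recover the tubule graph from an ER fluorescence image.

    Binarise (Otsu unless a fixed ``threshold`` is given), thin to a
    1-pixel skeleton, classify junction pixels (≥3 skeleton neighbours)
    and endpoints as nodes, and trace the skeleton paths between them as
    edges.  Spur branches shorter than ``spur_px`` pixels (thinning
    artifacts) are removed, and pass-through (degree-2) nodes left behind
    are merged into their through-edge.  Junction nodes closer than
    ``junction_merge_px`` are contracted into one: thinning a blurred
    three-way meeting of tubules frequently fractures it into several
    junction pixels joined by 1-2 px paths, whose micro-faces would
    otherwise inflate the polygon count.  Edge geometry follows the
    traced pixel path, so the graph keeps its planar embedding.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu
    from skimage.morphology import skeletonize

    img = np.asarray(er_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel frame")
    px_um = pixel_size_nm / 1000.0
    if threshold is None:
        if np.ptp(img) == 0:
            return ERGraph()
        threshold = threshold_otsu(img)
    binary = img > threshold
    if not binary.any():
        return ERGraph()
    skel = skeletonize(binary)
    if not skel.any():
        return ERGraph()

    nbr = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3), dtype=np.int8),
                           mode="constant") - skel.astype(np.int8)
    node_px = skel & ((nbr >= 3) | (nbr == 1))
    node_lbl, n_nodes = ndimage.label(node_px, structure=np.ones((3, 3)))

    g = nx.MultiGraph()
    # centroid positions per node cluster
    for lab in range(1, n_nodes + 1):
        ys, xs = np.nonzero(node_lbl == lab)
        g.add_node(lab - 1, pos=(float((xs.mean() + 0.5) * px_um),
                                 float((ys.mean() + 0.5) * px_um)))

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    H, W = skel.shape

    def neighbors(y, x):
        for dy, dx in offsets:
            ny, nx_ = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx_ < W and skel[ny, nx_]:
                yield ny, nx_

    visited = np.zeros_like(skel, dtype=bool)

    def trace(start, prev_node_px):
        """Walk along non-node skeleton pixels from ``start``; return
        (path pixels, terminal node label or None)."""
        path = [start]
        visited[start] = True
        prev = prev_node_px
        cur = start
        while True:
            nxt = None
            for nb in neighbors(*cur):
                if node_lbl[nb]:
                    if nb != prev:
                        return path, node_lbl[nb] - 1
                elif not visited[nb] and nb != prev:
                    nxt = nb
                    break
            if nxt is None:
                return path, None
            visited[nxt] = True
            prev, cur = cur, nxt
            path.append(cur)

    def path_geometry(a_node, path, b_node):
        pts = []
        if a_node is not None:
            pts.append(g.nodes[a_node]["pos"])
        pts += [((x + 0.5) * px_um, (y + 0.5) * px_um) for y, x in path]
        if b_node is not None:
            pts.append(g.nodes[b_node]["pos"])
        return np.array(pts, dtype=float)

    direct_contacts: set[tuple[int, int]] = set()
    for lab in range(1, n_nodes + 1):
        ys, xs = np.nonzero(node_lbl == lab)
        cluster = set(zip(ys.tolist(), xs.tolist()))
        for py, px_i in cluster:
            for nb in neighbors(py, px_i):
                if node_lbl[nb]:
                    other = node_lbl[nb] - 1
                    # direct node-to-node contact between distinct clusters
                    # (recorded once per cluster pair)
                    pair = (lab - 1, other)
                    if other > lab - 1 and pair not in direct_contacts:
                        direct_contacts.add(pair)
                        geom = np.array([g.nodes[lab - 1]["pos"],
                                         g.nodes[other]["pos"]])
                        length = float(np.hypot(*(geom[1] - geom[0])))
                        if length > 0:
                            g.add_edge(lab - 1, other, length=length,
                                       geometry=geom)
                    continue
                if visited[nb]:
                    continue
                path, end = trace(nb, (py, px_i))
                geom = path_geometry(lab - 1, path, end)
                length = float(np.sum(np.hypot(*np.diff(geom, axis=0).T)))
                if end is not None:
                    g.add_edge(lab - 1, end, length=length, geometry=geom)
                # dead-end paths not terminating at a node: dropped (dangling
                # fragments below the endpoint-classification scale)

    # components with no junction/endpoint pixels are pure loops
    rem = skel & ~visited & ~node_px
    loop_lbl, n_loops = ndimage.label(rem, structure=np.ones((3, 3)))
    for lab in range(1, n_loops + 1):
        ys, xs = np.nonzero(loop_lbl == lab)
        start = (ys[0], xs[0])
        nid = g.number_of_nodes()
        g.add_node(nid, pos=(float((start[1] + 0.5) * px_um),
                             float((start[0] + 0.5) * px_um)))
        # walk the loop
        path = [start]
        visited[start] = True
        prev, cur = None, start
        while True:
            nxt = None
            for nb in neighbors(*cur):
                if loop_lbl[nb] == lab and not visited[nb]:
                    nxt = nb
                    break
            if nxt is None:
                break
            visited[nxt] = True
            prev, cur = cur, nxt
            path.append(cur)
        geom = np.array([((x + 0.5) * px_um, (y + 0.5) * px_um)
                         for y, x in path + [start]], dtype=float)
        length = float(np.sum(np.hypot(*np.diff(geom, axis=0).T)))
        if length > 0:
            g.add_edge(nid, nid, length=length, geometry=geom)

    er = ERGraph(g)
    _remove_spurs(er, spur_px * px_um)
    _merge_close_junctions(er, junction_merge_px * px_um)
    _merge_degree2(er)
    return er


def _remove_spurs(er: ERGraph, max_len_um: float) -> None:
    """Iteratively drop short dangling edges (skeletonization artifacts)."""
    g = er.g
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v:
                continue
            if (g.degree(u) == 1 or g.degree(v) == 1) and d["length"] < max_len_um:
                g.remove_edge(u, v, k)
                changed = True
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])


def _merge_close_junctions(er: ERGraph, tol_um: float) -> None:
    """Contract edges shorter than ``tol_um`` (thinning micro-structure at
    junctions), then drop the degenerate loops and duplicated short
    parallels the contraction leaves behind."""
    g = er.g
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v or d["length"] >= tol_um:
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
            changed = True
    # degenerate self-loops from collapsed micro-faces
    for u, v, k, d in list(g.edges(keys=True, data=True)):
        if u == v and d["length"] < 2 * tol_um:
            g.remove_edge(u, v, k)
    # duplicated short parallels (both arcs short ⇒ a collapsed micro-face,
    # not a genuine polygon): keep one arc per pair
    by_pair: dict[tuple[int, int], list] = {}
    for u, v, k, d in list(g.edges(keys=True, data=True)):
        if u != v:
            by_pair.setdefault((min(u, v), max(u, v)), []).append((u, v, k, d))
    for lst in by_pair.values():
        short = [e for e in lst if e[3]["length"] < 2 * tol_um]
        if len(short) >= 2:
            for u, v, k, _ in short[1:]:
                g.remove_edge(u, v, k)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])


def _merge_degree2(er: ERGraph) -> None:
    """Splice out pass-through nodes, concatenating their two edges."""
    g = er.g
    for n in list(g.nodes):
        if g.degree(n) != 2:
            continue
        inc = list(g.edges(n, keys=True, data=True))
        if len(inc) != 2:
            continue  # a self-loop at n counts degree 2 with one edge
        (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
        a = v1 if u1 == n else u1
        b = v2 if u2 == n else u2
        if a == n or b == n:
            continue
        g1 = er.edge_geometry(u1, v1, k1)
        g2 = er.edge_geometry(u2, v2, k2)
        npos = np.array(g.nodes[n]["pos"])
        if not np.allclose(g1[-1], npos):
            g1 = g1[::-1]
        if not np.allclose(g2[0], npos):
            g2 = g2[::-1]
        geom = np.vstack([g1, g2[1:]])
        g.remove_edge(u1, v1, k1)
        g.remove_edge(u2, v2, k2)
        g.remove_node(n)
        g.add_edge(a, b, length=d1["length"] + d2["length"], geometry=geom)


# ---------------------------------------------------------------------------
# connectivity → mobility
# ---------------------------------------------------------------------------

def connectivity_mobility_curve(base_graph: ERGraph,
                                prune_fractions: Sequence[float],
                                frap_protocol: dict,
                                seed: int,
                                n_seeds: int = 3):
    """In-silico FRAP across connectivity levels.

    For each prune fraction, prunes ``base_graph``, simulates ``n_seeds``
    photobleach movies under ``frap_protocol`` (see
    :func:`ernetics.synthkit.simulate_photobleach_movie`), fits each
    recovery, and returns one row per condition with the seed-averaged
    fitted mobile fraction and half-recovery time.  The mobile fraction
    is, as in the bench protocol, the fraction exchanging on the
    protocol's timescale: finite ``duration_s`` is part of the readout.

    ``frap_protocol`` keys: ``roi`` and ``reference_roi`` (:class:`Roi`),
    ``diffusion_um2_s``, ``immobile_fraction``, ``n_particles``,
    ``duration_s``, ``config`` (:class:`ImagingConfig`) and optional
    ``pre_frames``.
    """
    import pandas as pd

    from . import synthkit

    rows = []
    for i, pf in enumerate(prune_fractions):
        ms, ths = [], []
        for j in range(n_seeds):
            pruned = prune_edges(base_graph, pf,
                                 seed=seed + 1000 * (j + 1) + i)
            fit = synthkit.in_silico_frap(pruned, frap_protocol,
                                          seed=seed + 100 * j + i)
            ms.append(fit.mobile_fraction)
            ths.append(fit.t_half_s if fit.t_half_s is not None else np.nan)
        rows.append({"prune_fraction": pf,
                     "mobile_fraction_fit": float(np.mean(ms)),
                     "t_half_fit_s": float(np.nanmean(ths)) if not
                     np.all(np.isnan(ths)) else np.nan})
    return pd.DataFrame(rows)
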