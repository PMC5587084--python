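"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's own face/geometry code paths:
faces are enumerated by walking the combinatorial planar embedding
(rotation system from node coordinates), and segment crossings are
tested pair-by-pair with elementary geometry.
"""

from __future__ import annotations

import numpy as np


def enumerate_faces(graph) -> list[dict]:
    """Enumerate the faces of a planar-embedded graph by walking its
    rotation system.

    Each edge contributes two directed half-edges.  At the head of a
    half-edge the walk continues with the next half-edge clockwise from
    the reversed one (ordering neighbours by angle), which traverses
    interior faces counterclockwise (positive signed area, y-up
    convention) and each component's outer face clockwise.  Returns one
    record per closed walk with its signed area and vertex cycle.
    Parallel edges and self-loops are resolved by keying half-edges with
    the edge key and walking their polyline geometry.
    """
    g = graph.g
    pos = {n: np.asarray(p, dtype=float) for n, p in g.nodes(data="pos")}

    # directed half-edges: (u, v, key, end) with end in {0, 1} marking
    # direction along the stored geometry
    half_edges = []
    for u, v, k in g.edges(keys=True):
        half_edges.append((u, v, k, 0))
        half_edges.append((v, u, k, 1))

    def departure_angle(he):
        u, v, k, end = he
        geom = graph.edge_geometry(u, v, k)
        if np.allclose(geom[0], pos[u]) and not (
                np.allclose(geom[0], geom[-1]) and u == v and end == 1):
            p0, p1 = geom[0], geom[1]
        else:
            p0, p1 = geom[-1], geom[-2]
        if u == v:
            # self-loop: the two half-edges leave along opposite ends
            p0, p1 = (geom[0], geom[1]) if end == 0 else (geom[-1], geom[-2])
        d = p1 - p0
        return np.arctan2(d[1], d[0])

    def arrival_angle(he):
        u, v, k, end = he
        geom = graph.edge_geometry(u, v, k)
        if u == v:
            p0, p1 = (geom[-1], geom[-2]) if end == 0 else (geom[0], geom[1])
        elif np.allclose(geom[-1], pos[v]):
            p0, p1 = geom[-1], geom[-2]
        else:
            p0, p1 = geom[0], geom[1]
        d = p1 - p0
        return np.arctan2(d[1], d[0])

    # rotation system: half-edges departing each node, ordered by angle
    departing: dict[int, list] = {}
    for he in half_edges:
        departing.setdefault(he[0], []).append(he)
    for n in departing:
        departing[n].sort(key=departure_angle)

    def next_half_edge(he):
        """Successor of ``he`` in its face walk."""
        u, v, k, end = he
        back_angle = arrival_angle(he)
        ring = departing[v]
        angles = [departure_angle(x) for x in ring]
        # find the departing half-edge immediately clockwise of back_angle,
        # skipping the exact reversal of he
        best, best_delta = None, None
        for x, a in zip(ring, angles):
            if x == (v, u, k, 1 - end):
                continue
            delta = (back_angle - a) % (2 * np.pi)
            if delta <= 1e-12:
                delta = 2 * np.pi
            if best is None or delta < best_delta:
                best, best_delta = x, delta
        if best is None:  # dead end: bounce back
            best = (v, u, k, 1 - end)
        return best

    visited = set()
    faces = []
    for he0 in half_edges:
        if he0 in visited:
            continue
        walk = []
        pts = []
        he = he0
        while he not in visited:
            visited.add(he)
            walk.append(he)
            u, v, k, end = he
            geom = graph.edge_geometry(u, v, k)
            if not np.allclose(geom[0], pos[u]) or (u == v and end == 1):
                geom = geom[::-1]
            pts.append(geom[:-1])
            he = next_half_edge(he)
        poly = np.vstack(pts)
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        faces.append({"walk": walk, "signed_area": area})
    return faces


def count_interior_faces(graph, min_area: float = 1e-9) -> int:
    """Interior (closed-polygon) count by face enumeration.

    Under the walk rule above, every interior face is traversed with
    positive signed area and each component's outer face with negative
    signed area (tree components yield a single zero-area walk).
    """
    faces = enumerate_faces(graph)
    return sum(1 for f in faces if f["signed_area"] > min_area)


def segment_crossings(graph) -> int:
    """Count crossing pairs among straight edge segments by elementary
    geometry (orientation tests), ignoring contacts at shared nodes."""

    def orient(p, q, r):
        return np.sign((q[0] - p[0]) * (r[1] - p[1])
                       - (q[1] - p[1]) * (r[0] - p[0]))

    pos = {n: np.asarray(p, float) for n, p in graph.g.nodes(data="pos")}
    edges = [(u, v) for u, v, _ in graph.g.edges(keys=True)]
    n_cross = 0
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            a, b = edges[i]
            c, d = edges[j]
            if {a, b} & {c, d}:
                continue
            p1, p2, p3, p4 = pos[a], pos[b], pos[c], pos[d]
            o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
            o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
            if o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4):
                n_cross += 1
    return n_cross
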