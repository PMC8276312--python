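"""Degree-0/1 Vietoris-Rips persistent homology with representative cycles.

The Vietoris-Rips filtration on a Euclidean point cloud inserts a simplex at
the scale equal to its diameter (an edge {x_i, x_j} enters at r = |x_i - x_j|).
Degree-0 bars are computed by Kruskal-style union-find over the sorted edges
(every vertex is born at 0; a component dies when the merging edge appears).
Degree-1 bars come from column reduction of the triangle boundary matrix over
GF(2): columns are processed in filtration order and each column is XOR-ed
against previously stored columns until its pivot (largest edge index) is
free.  The resulting (pivot edge, triangle) pairs are exactly the persistence
pairs of the full boundary-matrix reduction restricted to degree 1, because
reduction never mixes columns of different dimension.  Columns are Python
integers used as bitsets, which keeps the inner loop in C.

All classes in degree 1 of a finite cloud die at a finite scale (the complex
becomes a full simplex), so every degree-1 bar is finite.

Representative cycles: the class born at a positive edge e = {u, v} is
represented by e together with any u-v path through strictly earlier edges;
we take the shortest such path (Dijkstra on edges below the birth scale),
which yields an approximate-shortest representative whose edges all have
length <= the birth scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs for one homology degree."""

    degree: int
    points: np.ndarray  # shape (n, 2), birth < death

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def persistences(self) -> np.ndarray:
        return self.points[:, 1] - self.points[:, 0]

    def max_persistence_point(self) -> np.ndarray:
        if len(self.points) == 0:
            raise ValueError("empty diagram")
        return self.points[int(np.argmax(self.persistences))]

    def multiplicity(self, point, tol: float = 1e-9) -> int:
        """Number of diagram points within ``tol`` (sup-norm) of ``point``."""
        if len(self.points) == 0:
            return 0
        delta = np.abs(self.points - np.asarray(point, dtype=float))
        return int(np.sum(np.max(delta, axis=1) <= tol))


@dataclass
class RepresentativeCycle:
    """A closed 1-cycle witnessing a degree-1 diagram point.

    ``edges`` index into the point cloud; ``vertex_sequence`` (filled by
    :func:`order_cycle`) traverses the loop once; ``time_indices`` maps the
    vertices back to original frame indices through the embedding;
    ``direction`` is ``"forward"`` or ``"backward"`` in original time.
    """

    diagram_point: tuple[float, float]
    edges: list[tuple[int, int]]
    vertex_sequence: list[int] = field(default_factory=list)
    time_indices: list[int] = field(default_factory=list)
    direction: str | None = None

    def to_json(self, path) -> None:
        import json

        payload = {
            "diagram_point": list(self.diagram_point),
            "edges": [list(e) for e in self.edges],
            "vertex_sequence": list(self.vertex_sequence),
            "time_indices": list(self.time_indices),
            "direction": self.direction,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "RepresentativeCycle":
        import json

        with open(path) as f:
            d = json.load(f)
        return cls(
            diagram_point=tuple(d["diagram_point"]),
            edges=[tuple(e) for e in d["edges"]],
            vertex_sequence=d["vertex_sequence"],
            time_indices=d["time_indices"],
            direction=d["direction"],
        )


def _edge_index(n: int, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    # condensed-distance-matrix index of edge (i < j)
    return n * i - i * (i + 1) // 2 + (j - i - 1)


def _h1_reduction(dm: np.ndarray, n: int):
    """Reduce the triangle boundary matrix; yield (birth_edge_rank, pairs).

    Returns ``(order, pairs)`` where ``order`` maps edge rank -> condensed
    edge index and ``pairs`` is a list of ``(edge_rank, birth, death)`` for
    every positive-persistence degree-1 bar.
    """
    from itertools import combinations

    m = n * (n - 1) // 2
    order = np.argsort(dm, kind="stable")
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(m)

    tris = np.fromiter(
        (x for c in combinations(range(n), 3) for x in c), dtype=np.int64
    ).reshape(-1, 3)
    if len(tris) == 0:
        return order, []
    i, j, k = tris[:, 0], tris[:, 1], tris[:, 2]
    r1 = rank[_edge_index(n, i, j)]
    r2 = rank[_edge_index(n, i, k)]
    r3 = rank[_edge_index(n, j, k)]
    rmax = np.maximum(np.maximum(r1, r2), r3)
    diam = dm[order[rmax]]
    # filtration order: by diameter, ties broken by max edge rank
    torder = np.lexsort((rmax, diam))

    sorted_w = dm[order]
    pivot_of: dict[int, int] = {}
    pairs: list[tuple[int, float, float]] = []
    for t in torder:
        col = (1 << int(r1[t])) | (1 << int(r2[t])) | (1 << int(r3[t]))
        while col:
            p = col.bit_length() - 1
            stored = pivot_of.get(p)
            if stored is None:
                pivot_of[p] = col
                b = float(sorted_w[p])
                d = float(diam[t])
                if d > b:
                    pairs.append((p, b, d))
                break
            col ^= stored
    return order, pairs


def _h0_bars(dm: np.ndarray, n: int) -> np.ndarray:
    """Degree-0 bars via union-find over edges sorted by length."""
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    order = np.argsort(dm, kind="stable")
    deaths = []
    # recover (i, j) from condensed index
    ii, jj = np.triu_indices(n, 1)
    for e in order:
        ra, rb = find(int(ii[e])), find(int(jj[e]))
        if ra != rb:
            parent[ra] = rb
            deaths.append(float(dm[e]))
            if len(deaths) == n - 1:
                break
    bars = [(0.0, d) for d in deaths] + [(0.0, np.inf)]
    return np.array(bars)


def vr_diagram(points: np.ndarray, max_degree: int = 1) -> list[PersistenceDiagram]:
    """Persistence diagrams of the Vietoris-Rips filtration up to ``max_degree``.

    Parameters
    ----------
    points : ndarray, shape (n, d)
        Point cloud with the Euclidean metric.
    max_degree : int
        Highest homology degree computed (0 or 1).

    Returns
    -------
    list of PersistenceDiagram, one per degree ``0..max_degree``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) == 0:
        raise ValueError("empty point cloud")
    if not np.all(np.isfinite(points)):
        raise ValueError("point cloud contains non-finite coordinates")
    if max_degree not in (0, 1):
        raise ValueError("only degrees 0 and 1 are supported")

    n = len(points)
    if n == 1:
        out = [PersistenceDiagram(0, np.array([[0.0, np.inf]]))]
        if max_degree >= 1:
            out.append(PersistenceDiagram(1, np.empty((0, 2))))
        return out

    dm = pdist(points)
    out = [PersistenceDiagram(0, _h0_bars(dm, n))]
    if max_degree >= 1:
        _, pairs = _h1_reduction(dm, n)
        pts = np.array([(b, d) for _, b, d in pairs]).reshape(-1, 2)
        out.append(PersistenceDiagram(1, pts))
    return out


def significant_features(
    diagram: PersistenceDiagram, ratio: float = 0.3
) -> list[tuple[float, float]]:
    """Diagram points whose persistence is >= ``ratio`` times the maximum.

    The underlying study never pins down "significant"; this declared rule
    (default ratio 0.3 of the maximal persistence in the diagram) is the
    package-wide convention and is configurable.
    """
    if len(diagram) == 0:
        return []
    pers = diagram.persistences
    cutoff = ratio * pers.max()
    keep = diagram.points[pers >= cutoff]
    keep = keep[np.argsort(-(keep[:, 1] - keep[:, 0]))]
    return [tuple(p) for p in keep]


def representative_cycle(
    points: np.ndarray,
    target: tuple[float, float],
    tol: float = 1e-8,
) -> RepresentativeCycle:
    """A 1-cycle generating the degree-1 class of ``target`` at its birth scale.

    The birth edge found by the reduction is completed into a loop by the
    shortest path between its endpoints through strictly earlier edges, so
    every edge of the cycle has length <= the birth scale.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    dm = pdist(points)
    order, pairs = _h1_reduction(dm, n)
    a, b = float(target[0]), float(target[1])
    scale = max(1.0, abs(a), abs(b))
    match = [
        p for p in pairs if abs(p[1] - a) <= tol * scale and abs(p[2] - b) <= tol * scale
    ]
    if not match:
        raise ValueError(f"target {target} not present in the degree-1 diagram")
    edge_rank, birth, death = match[0]

    ii, jj = np.triu_indices(n, 1)
    e = int(order[edge_rank])
    u, v = int(ii[e]), int(jj[e])

    # graph of strictly earlier edges
    earlier = order[:edge_rank]
    gi, gj, gw = ii[earlier], jj[earlier], dm[earlier]
    graph = coo_matrix((gw, (gi, gj)), shape=(n, n)).tocsr()
    dist, pred = dijkstra(
        graph, directed=False, indices=u, return_predecessors=True
    )
    if not np.isfinite(dist[v]):
        raise RuntimeError("no path closing the birth edge; inconsistent reduction")
    path = [v]
    while path[-1] != u:
        path.append(int(pred[path[-1]]))
    path.reverse()  # u .. v
    edges = [(path[t], path[t + 1]) for t in range(len(path) - 1)] + [(v, u)]
    return RepresentativeCycle(diagram_point=(birth, death), edges=edges)


def order_cycle(cycle: RepresentativeCycle, embedding=None) -> RepresentativeCycle:
    """Fill ``vertex_sequence``, ``time_indices`` and ``direction``.

    The edges must form a single closed loop (each vertex meets exactly two
    edges).  The loop is oriented so that the majority of consecutive vertex
    pairs increase in time (ties toward increasing), which recovers the
    trajectory order of the series that produced the cloud; ``direction``
    records whether that orientation's steps are majority-increasing
    ("forward", the generic case) or not.  Note this is traversal order
    within the analyzed series; the behavioral direction of an undulatory
    gait (wave running head-to-tail vs tail-to-head) is inferred from the
    poses themselves at synthesis time.

    ``embedding`` may be a WindowedSeries (its ``start_index`` maps vertices
    to frames) or None, in which case vertex indices are the time indices.
    """
    adj: dict[int, list[int]] = {}
    for i, j in cycle.edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    if any(len(nb) != 2 for nb in adj.values()):
        raise ValueError("cycle edges do not form a single closed loop")

    start = min(adj)
    seq = [start]
    prev = None
    while True:
        nxt = [w for w in adj[seq[-1]] if w != prev]
        prev = seq[-1]
        step = nxt[0]
        if step == start:
            break
        seq.append(step)
    if len(seq) != len(adj):
        raise ValueError("cycle edges do not form a single closed loop")

    if embedding is not None:
        times = [embedding.start_index(v) for v in seq]
    else:
        times = list(seq)

    n = len(seq)

    def n_increasing(ts):
        return sum(ts[(t + 1) % n] > ts[t] for t in range(n))

    if 2 * n_increasing(times) < n:  # flip to the majority-increasing orientation
        seq = [seq[0]] + seq[:0:-1]
        times = [times[0]] + times[:0:-1]
    inc = n_increasing(times)
    dec = sum(times[(t + 1) % n] < times[t] for t in range(n))
    cycle.vertex_sequence = seq
    cycle.time_indices = times
    cycle.direction = "forward" if inc >= dec else "backward"
    return cycle


def maxmin_subsample(
    points: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Farthest-point (maxmin) subsample of ``k`` points.

    Greedy landmark selection: start from a seeded random point, repeatedly
    add the point farthest from the chosen set.  The selected landmarks cover
    the cloud within its k-th packing radius, which preserves large-scale
    topology while bounding the Vietoris-Rips cost.  Returns ``(subset
    points, indices)``; the indices are sorted to preserve temporal order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k >= n:
        return points, np.arange(n)
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    chosen = [first]
    d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    idx = np.sort(np.array(chosen))
    return points[idx], idx


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix (convenience wrapper)."""
    return squareform(pdist(np.asarray(points, dtype=float)))
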