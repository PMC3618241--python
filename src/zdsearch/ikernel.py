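"""iKernel: concentric-ring indexing with best-first search.

Each cluster's members, sorted by distance to the centroid, are grouped into
concentric rings of ``g`` points.  Grouping starts from the *outermost*
point, so only the innermost ring of a cluster may hold fewer than ``g``
members; the search seeds itself with outermost rings, and full rings on the
outside keep that seeding informative.  A ring stores the min/max member
distances to the centroid (its inner/outer radii), the tightest annulus
bounds derivable from stored data.

Search is best-first over a priority queue.  Ring entries act as gateways to
everything centroid-ward of them, so they are keyed by the cluster-tail
lower bound ``max(0, d - outer)`` (``d`` the query-to-centroid distance):
any point reachable through the ring lies within centroid-distance
``outer``, hence at least ``d - outer`` from the query.  Popping a ring
evaluates its members (pushed at true distance) and admits the next-inner
ring; popping a point emits it.  Keys therefore pop in non-decreasing order
and every emitted point is exact.  For a query outside the cluster this key
equals the ring's annulus MPD, the configuration depicted in the method's
worked traces; :func:`mpd` exposes the full annulus bound.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ParameterError
from .partitioning import DescriptorDatabase, Partition, distance
from .result import SearchResult

DEFAULT_G = 50


@dataclass
class Ring:
    """One annulus of a cluster; larger ``ring_index`` = farther out."""

    cluster_index: int
    ring_index: int
    member_idx: np.ndarray
    member_d: np.ndarray  # distances to the cluster centroid
    inner: float
    outer: float


@dataclass
class IKernelIndex:
    db: DescriptorDatabase
    partition: Partition
    g: int
    #: per cluster: rings ordered innermost -> outermost
    rings: list[list[Ring]]


def build_ikernel(db: DescriptorDatabase, partition: Partition, g: int = DEFAULT_G) -> IKernelIndex:
    """Group each cluster into rings of ``g`` points, outermost-first."""
    if g < 1:
        raise ParameterError(f"g must be >= 1, got {g}")
    all_rings: list[list[Ring]] = []
    for c in partition.clusters:
        d = np.linalg.norm(db.X[c.member_idx] - c.center, axis=1)
        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        idx_sorted = c.member_idx[order]
        s = idx_sorted.size
        bounds = list(range(s, 0, -g))[::-1]  # ring starts, outermost chunk full
        starts = [b - g if b - g > 0 else 0 for b in bounds]
        rings = []
        for j, (lo, hi) in enumerate(zip(starts, bounds), start=1):
            rings.append(
                Ring(
                    cluster_index=c.index,
                    ring_index=j,
                    member_idx=idx_sorted[lo:hi],
                    member_d=d_sorted[lo:hi],
                    inner=float(d_sorted[lo]),
                    outer=float(d_sorted[hi - 1]),
                )
            )
        all_rings.append(rings)
    return IKernelIndex(db=db, partition=partition, g=g, rings=all_rings)


def mpd(q, ring: Ring, centroid) -> float:
    """Minimal possible distance from ``q`` to any point of ``ring``.

    With ``d = dist(q, centroid)``: ``d - outer`` beyond the annulus,
    ``inner - d`` inside of it, else 0.  A lower bound on the true distance
    to every ring member by the triangle inequality.
    """
    d = distance(q, centroid)
    if d > ring.outer:
        return d - ring.outer
    if d < ring.inner:
        return ring.inner - d
    return 0.0


_RING, _POINT = 0, 1  # heap tie-break: rings before points at equal key


def _best_first(index: IKernelIndex, q, stop):
    """Shared best-first loop; ``stop(n_out, key)`` decides termination.

    Yields nothing; returns (ids, dists, n_eval, popped_keys).
    """
    q = np.asarray(q, dtype=float)
    d_ref = cdist(q[None, :], index.partition.centers)[0]
    heap: list = []
    for i, rings in enumerate(index.rings):
        if rings:
            outer_ring = rings[-1]
            key = max(0.0, float(d_ref[i]) - outer_ring.outer)
            heapq.heappush(heap, (key, _RING, (i, outer_ring.ring_index), len(rings) - 1))
    out_ids: list[str] = []
    out_d: list[float] = []
    n_eval = 0
    popped: list[float] = []
    while heap:
        key, kind, tie, payload = heapq.heappop(heap)
        if stop(len(out_ids), key):
            break
        popped.append(key)
        if kind == _RING:
            i, _ = tie
            pos = payload
            ring = index.rings[i][pos]
            dd = np.linalg.norm(index.db.X[ring.member_idx] - q, axis=1)
            n_eval += ring.member_idx.size
            for row, dist_q in zip(ring.member_idx, dd):
                heapq.heappush(heap, (float(dist_q), _POINT, index.db.ids[row], row))
            if pos > 0:
                nxt = index.rings[i][pos - 1]
                nkey = max(0.0, float(d_ref[i]) - nxt.outer)
                heapq.heappush(heap, (nkey, _RING, (i, nxt.ring_index), pos - 1))
        else:
            out_ids.append(tie)
            out_d.append(key)
    return out_ids, np.asarray(out_d), n_eval, np.asarray(popped)


def knn_ikernel(index: IKernelIndex, q, k: int) -> SearchResult:
    """Exact k nearest neighbors by best-first ring traversal."""
    n = len(index.db)
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    ids, dists, n_eval, popped = _best_first(index, q, stop=lambda n_out, key: n_out >= k)
    return SearchResult(
        ids=ids, distances=dists, n_distance_evaluations=n_eval, n_db=n, popped_keys=popped
    )


def range_ikernel(index: IKernelIndex, q, theta: float) -> SearchResult:
    """All points at distance strictly below ``theta``.

    Same traversal as the k-NN search, terminated as soon as the popped key
    reaches ``theta``: every point closer than ``theta`` must pop before any
    entry with key >= ``theta``, so the cut-off is exact.
    """
    if theta < 0:
        raise ParameterError(f"theta must be >= 0, got {theta}")
    n = len(index.db)
    ids, dists, n_eval, popped = _best_first(index, q, stop=lambda n_out, key: key >= theta)
    return SearchResult(
        ids=ids, distances=dists, n_distance_evaluations=n_eval, n_db=n, popped_keys=popped
    )
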