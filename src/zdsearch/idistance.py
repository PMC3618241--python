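"""iDistance: one-dimensional key indexing for exact high-dimensional search.

Every point ``p`` in cluster ``i`` is mapped to the scalar key

    y = i * C + dist(p, O_i)

where ``O_i`` is the cluster's reference point and ``C`` a stretch constant
larger than every cluster radius, so cluster key intervals
``[i*C, i*C + dist_max_i]`` never overlap and one sorted key sequence serves
the whole database.  A k-NN query grows a search radius ``r`` in steps of
``delta_r``; at each step only clusters whose ball can intersect the query
ball are scanned, and within a cluster only the key sub-interval
``[i*C + max(0, d_i - r), i*C + min(dist_max_i, d_i + r)]`` (``d_i`` the
query-to-reference distance) is touched.  The reverse triangle inequality
makes the final answer exact.

The original scheme stores keys in a B+-tree; an in-memory sorted array with
binary search has the identical contract and is used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import IndexBuildError, ParameterError
from .partitioning import DescriptorDatabase, Partition, distance
from .result import SearchResult, order_by_distance

DEFAULT_C = 4.0
DEFAULT_DELTA_R = 0.2


def idistance_key(p, i: int, O_i, C: float = DEFAULT_C) -> float:
    """The scalar key ``i * C + dist(p, O_i)`` of a point in cluster ``i``."""
    if C <= 0:
        raise ParameterError(f"C must be positive, got {C}")
    return i * C + distance(p, O_i)


@dataclass
class IDistanceIndex:
    db: DescriptorDatabase
    partition: Partition
    C: float
    #: per cluster: member distances to O_i, ascending
    cluster_d: list[np.ndarray]
    #: per cluster: database row indices aligned with ``cluster_d``
    cluster_idx: list[np.ndarray]

    @property
    def keys(self) -> np.ndarray:
        """The globally sorted key sequence over all points."""
        return np.concatenate(
            [i * self.C + d for i, d in enumerate(self.cluster_d)] or [np.empty(0)]
        )

    @property
    def key_ids(self) -> list[str]:
        return [self.db.ids[j] for idx in self.cluster_idx for j in idx]


def build_idistance(
    db: DescriptorDatabase, partition: Partition, C: float = DEFAULT_C
) -> IDistanceIndex:
    """Sort each cluster's members by distance to its reference point.

    Raises
    ------
    IndexBuildError
        If ``C`` does not exceed every cluster radius (key intervals of
        adjacent clusters would overlap), naming the violating cluster.
    """
    if C <= 0:
        raise ParameterError(f"C must be positive, got {C}")
    worst = max(partition.clusters, key=lambda c: c.dist_max)
    if worst.dist_max >= C:
        raise IndexBuildError(
            f"C={C} must exceed dist_max={worst.dist_max:.6g} of cluster {worst.index}; "
            "key intervals would overlap"
        )
    cluster_d, cluster_idx = [], []
    for c in partition.clusters:
        d = np.linalg.norm(db.X[c.member_idx] - c.center, axis=1)
        order = np.argsort(d, kind="stable")
        cluster_d.append(d[order])
        cluster_idx.append(c.member_idx[order])
    return IDistanceIndex(db=db, partition=partition, C=C, cluster_d=cluster_d, cluster_idx=cluster_idx)


def _scan_new(index: IDistanceIndex, i: int, a: float, b: float, visited: list) -> np.ndarray:
    """Row indices in cluster ``i`` with reference-distance in [a, b] that were
    not scanned before; widens the cluster's visited frontier."""
    d = index.cluster_d[i]
    lo = int(np.searchsorted(d, a, side="left"))
    hi = int(np.searchsorted(d, b, side="right"))
    if visited[i] is None:
        visited[i] = (lo, hi)
        return index.cluster_idx[i][lo:hi]
    vlo, vhi = visited[i]
    new = np.concatenate([index.cluster_idx[i][lo:vlo], index.cluster_idx[i][vhi:hi]])
    visited[i] = (min(lo, vlo), max(hi, vhi))
    return new


def knn_idistance(
    index: IDistanceIndex, q, k: int, delta_r: float = DEFAULT_DELTA_R
) -> SearchResult:
    """Exact k nearest neighbors via expanding-radius key scans.

    The radius starts at ``delta_r`` and grows by ``delta_r`` per iteration;
    partially scanned clusters resume from their visited frontier, so no
    point's distance is computed twice.  The search stops as soon as the
    k-th best distance is at most ``r``, at which point unscanned points are
    provably farther.  Ties at the k-th distance go to the lower id.
    """
    n = len(index.db)
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    if delta_r <= 0:
        raise ParameterError(f"delta_r must be positive, got {delta_r}")
    q = np.asarray(q, dtype=float)
    d_ref = cdist(q[None, :], index.partition.centers)[0]
    dist_max = np.array([c.dist_max for c in index.partition.clusters])
    visited: list = [None] * index.partition.M
    cand_idx: list[np.ndarray] = []
    cand_d: list[np.ndarray] = []
    n_eval = 0
    n_seen = 0
    r = delta_r
    while True:
        for i in range(index.partition.M):
            if d_ref[i] - r > dist_max[i]:
                continue
            a = max(0.0, d_ref[i] - r)
            b = min(float(dist_max[i]), d_ref[i] + r)
            if b < a:
                continue
            new = _scan_new(index, i, a, b, visited)
            if new.size:
                cand_idx.append(new)
                cand_d.append(np.linalg.norm(index.db.X[new] - q, axis=1))
                n_eval += new.size
                n_seen += new.size
        if n_seen >= k:
            all_d = np.concatenate(cand_d)
            kth = np.partition(all_d, k - 1)[k - 1]
            if kth <= r:
                break
        if n_seen == n:
            break
        r += delta_r
    all_idx = np.concatenate(cand_idx)
    all_d = np.concatenate(cand_d)
    ids = np.asarray(index.db.ids, dtype=str)[all_idx]
    order = order_by_distance(all_d, ids)[:k]
    return SearchResult(
        ids=list(ids[order]),
        distances=all_d[order],
        n_distance_evaluations=n_eval,
        n_db=n,
    )


def range_idistance(index: IDistanceIndex, q, theta: float) -> SearchResult:
    """All points at distance strictly less than ``theta``, ascending.

    One pass with fixed radius ``theta`` over every cluster whose ball can
    intersect the query ball.
    """
    if theta < 0:
        raise ParameterError(f"theta must be >= 0, got {theta}")
    n = len(index.db)
    q = np.asarray(q, dtype=float)
    d_ref = cdist(q[None, :], index.partition.centers)[0]
    hits_idx: list[np.ndarray] = []
    hits_d: list[np.ndarray] = []
    n_eval = 0
    for i, c in enumerate(index.partition.clusters):
        if d_ref[i] - theta > c.dist_max:
            continue
        a = max(0.0, d_ref[i] - theta)
        b = min(c.dist_max, d_ref[i] + theta)
        if b < a:
            continue
        d = index.cluster_d[i]
        lo = int(np.searchsorted(d, a, side="left"))
        hi = int(np.searchsorted(d, b, side="right"))
        rows = index.cluster_idx[i][lo:hi]
        if rows.size:
            dd = np.linalg.norm(index.db.X[rows] - q, axis=1)
            n_eval += rows.size
            keep = dd < theta
            hits_idx.append(rows[keep])
            hits_d.append(dd[keep])
    if hits_idx:
        all_idx = np.concatenate(hits_idx)
        all_d = np.concatenate(hits_d)
    else:
        all_idx = np.empty(0, dtype=int)
        all_d = np.empty(0)
    ids = np.asarray(index.db.ids, dtype=str)[all_idx]
    order = order_by_distance(all_d, ids)
    return SearchResult(
        ids=list(ids[order]),
        distances=all_d[order],
        n_distance_evaluations=n_eval,
        n_db=n,
    )
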