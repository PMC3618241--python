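"""Reduced-dimension (prefix) indexing with full-distance re-ranking.

Leading 3DZD invariants carry global shape; trailing ones add fine detail.
Building the index on only the first ``m`` coordinates (default 60, about
half of the 121) therefore keeps most of the discriminative signal while
making every index operation cheaper.  Two search modes:

* top-k: retrieve ``k * multiplier`` candidates (default 10x) under the
  prefix distance, then re-rank those candidates by the full-dimension
  distance and keep the best ``k``.  Exact within the candidate set;
  coverage of the true top-k is high but below 1 in general.
* range: a prefix-distance range query with the same radius, then filtering
  candidates by full distance.  Since the prefix distance never exceeds the
  full distance, every true neighbor within ``theta`` survives stage 1 —
  this mode is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .idistance import DEFAULT_C, DEFAULT_DELTA_R, IDistanceIndex, build_idistance, knn_idistance, range_idistance
from .ikernel import DEFAULT_G, IKernelIndex, build_ikernel, knn_ikernel, range_ikernel
from .partitioning import DescriptorDatabase, Partition, kmeans_partition, random_partition
from .result import SearchResult, order_by_distance

DEFAULT_M_PREFIX = 60
DEFAULT_MULTIPLIER = 10


@dataclass
class ReducedIndex:
    """An iDistance or iKernel index over coordinate prefixes."""

    db: DescriptorDatabase  # full-dimension database, used for re-ranking
    m: int
    backend: str  # "idistance" | "ikernel"
    inner: IDistanceIndex | IKernelIndex
    multiplier: int = DEFAULT_MULTIPLIER
    delta_r: float = DEFAULT_DELTA_R


def build_reduced(
    db: DescriptorDatabase,
    m: int = DEFAULT_M_PREFIX,
    backend: str = "idistance",
    M: int = 64,
    partition_method: str = "kmeans",
    seed: int = 0,
    C: float = DEFAULT_C,
    g: int = DEFAULT_G,
    multiplier: int = DEFAULT_MULTIPLIER,
    delta_r: float = DEFAULT_DELTA_R,
    partition: Partition | None = None,
) -> ReducedIndex:
    """Build the inner index on prefix-truncated copies of the descriptors.

    ``partition`` may be supplied pre-built (it must partition the *prefix*
    database); otherwise one is built here with the requested method.
    """
    if not 1 <= m <= db.dim:
        raise ParameterError(f"m must be in [1, {db.dim}], got {m}")
    pdb = db.prefix(m)
    if partition is None:
        if partition_method == "kmeans":
            partition = kmeans_partition(pdb, M=M, seed=seed)
        elif partition_method == "random":
            partition = random_partition(pdb, M=M, seed=seed)
        else:
            raise ParameterError(f"unknown partition method {partition_method!r}")
    if backend == "idistance":
        inner: IDistanceIndex | IKernelIndex = build_idistance(pdb, partition, C=C)
    elif backend == "ikernel":
        inner = build_ikernel(pdb, partition, g=g)
    else:
        raise ParameterError(f"unknown backend {backend!r}")
    return ReducedIndex(db=db, m=m, backend=backend, inner=inner, multiplier=multiplier, delta_r=delta_r)


def _inner_knn(rindex: ReducedIndex, q_prefix, k: int) -> SearchResult:
    if rindex.backend == "idistance":
        return knn_idistance(rindex.inner, q_prefix, k, delta_r=rindex.delta_r)  # type: ignore[arg-type]
    return knn_ikernel(rindex.inner, q_prefix, k)  # type: ignore[arg-type]


def _inner_range(rindex: ReducedIndex, q_prefix, theta: float) -> SearchResult:
    if rindex.backend == "idistance":
        return range_idistance(rindex.inner, q_prefix, theta)  # type: ignore[arg-type]
    return range_ikernel(rindex.inner, q_prefix, theta)  # type: ignore[arg-type]


def _rerank(rindex: ReducedIndex, q, stage1: SearchResult) -> tuple[np.ndarray, np.ndarray, int]:
    """Full-dimension distances for stage-1 candidates.

    When ``m == dim`` the prefix distance already *is* the full distance, so
    no second evaluation happens and the stage-1 counts carry over.
    """
    ids = np.asarray(stage1.ids, dtype=str)
    if rindex.m == rindex.db.dim:
        return ids, stage1.distances, 0
    row_of = {i: r for r, i in enumerate(rindex.db.ids)}
    rows = np.asarray([row_of[i] for i in stage1.ids], dtype=int)
    q = np.asarray(q, dtype=float)
    full_d = np.linalg.norm(rindex.db.X[rows] - q, axis=1) if rows.size else np.empty(0)
    return ids, full_d, int(rows.size)


def extended_topk(rindex: ReducedIndex, q, k: int) -> SearchResult:
    """Two-stage top-k: prefix candidates (k x multiplier), full re-rank."""
    n = len(rindex.db)
    if not 1 <= k * rindex.multiplier <= n:
        raise ParameterError(
            f"k * multiplier = {k * rindex.multiplier} must be in [1, {n}]"
        )
    q = np.asarray(q, dtype=float)
    stage1 = _inner_knn(rindex, q[: rindex.m], k * rindex.multiplier)
    ids, full_d, n_stage2 = _rerank(rindex, q, stage1)
    order = order_by_distance(full_d, ids)[:k]
    return SearchResult(
        ids=list(ids[order]),
        distances=full_d[order],
        n_distance_evaluations=stage1.n_distance_evaluations + n_stage2,
        n_db=n,
    )


def extended_range(rindex: ReducedIndex, q, theta: float) -> SearchResult:
    """Two-stage range query; exact by the prefix-distance lower bound."""
    if theta < 0:
        raise ParameterError(f"theta must be >= 0, got {theta}")
    q = np.asarray(q, dtype=float)
    stage1 = _inner_range(rindex, q[: rindex.m], theta)
    ids, full_d, n_stage2 = _rerank(rindex, q, stage1)
    keep = full_d < theta
    ids, full_d = ids[keep], full_d[keep]
    order = order_by_distance(full_d, ids)
    return SearchResult(
        ids=list(ids[order]),
        distances=full_d[order],
        n_distance_evaluations=stage1.n_distance_evaluations + n_stage2,
        n_db=len(rindex.db),
    )


def coverage(approx: SearchResult, exact: SearchResult) -> float:
    """Fraction of the exact hit ids contained in the approximate hits."""
    if len(exact) == 0:
        raise ParameterError("coverage is undefined for an empty exact result")
    exact_ids = set(exact.ids)
    return len(exact_ids & set(approx.ids)) / len(exact_ids)
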