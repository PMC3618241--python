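"""Descriptor databases and reference-point partitioning.

Both indexes (iDistance, iKernel) start from the same structure: the
database is divided into ``M`` clusters, each with a reference point ``O_i``
and the maximum member-to-reference distance ``dist_max_i``.  References come
either from uniformly sampled database points or from k-means centroids;
k-means yields much better balanced clusters, which is what makes pruning
effective during search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .exceptions import DimensionMismatchError, ParameterError
from .zernike import InvariantVector

#: Cluster-count presets: data dimensionality, twice the dimensionality, and
#: two counts borrowed from protein-domain taxonomy (number of families /
#: domains), the defaults a full-scale descriptor database would use.
CLUSTER_COUNT_PRESETS = (121, 242, 498, 866)
DEFAULT_M = 866


def distance(a, b) -> float:
    """Euclidean distance between two equal-dimension vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass
class DescriptorDatabase:
    """An ordered collection of equal-dimension descriptors with unique ids."""

    ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.X.ndim != 2:
            raise ParameterError("descriptor matrix must be 2-D")
        if len(self.ids) != self.X.shape[0]:
            raise ParameterError("number of ids must match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError("descriptor ids must be unique")

    @classmethod
    def from_invariants(cls, vectors: list[InvariantVector]) -> "DescriptorDatabase":
        if not vectors:
            raise ParameterError("need at least one descriptor")
        return cls(ids=[v.id for v in vectors], X=np.vstack([v.values for v in vectors]))

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def prefix(self, m: int) -> "DescriptorDatabase":
        """A database over the first ``m`` coordinates (ids preserved)."""
        if not 1 <= m <= self.dim:
            raise ParameterError(f"prefix dimension must be in [1, {self.dim}], got {m}")
        return DescriptorDatabase(ids=list(self.ids), X=self.X[:, :m].copy())


@dataclass
class Cluster:
    index: int
    center: np.ndarray
    member_idx: np.ndarray  # row indices into the database
    dist_max: float


@dataclass
class Partition:
    """Disjoint, exhaustive division of a database into clusters."""

    method: str
    clusters: list[Cluster]
    labels: np.ndarray  # cluster index per database row

    @property
    def M(self) -> int:
        return len(self.clusters)

    @property
    def centers(self) -> np.ndarray:
        return np.vstack([c.center for c in self.clusters])


def _assemble(db: DescriptorDatabase, centers: np.ndarray, method: str) -> Partition:
    # nearest reference, ties broken toward the lowest cluster index
    # (argmin returns the first minimizer)
    labels = np.argmin(cdist(db.X, centers), axis=1)
    clusters = []
    for i in range(centers.shape[0]):
        members = np.flatnonzero(labels == i)
        d_max = float(np.linalg.norm(db.X[members] - centers[i], axis=1).max()) if members.size else 0.0
        clusters.append(Cluster(index=i, center=centers[i].copy(), member_idx=members, dist_max=d_max))
    return Partition(method=method, clusters=clusters, labels=labels)


def random_partition(db: DescriptorDatabase, M: int, seed: int = 0) -> Partition:
    """Uniformly sample ``M`` database points as references and assign the rest.

    Deterministic for a fixed seed.
    """
    if not 1 <= M <= len(db):
        raise ParameterError(f"M must be in [1, {len(db)}], got {M}")
    rng = np.random.default_rng(seed)
    ref_idx = np.sort(rng.choice(len(db), size=M, replace=False))
    return _assemble(db, db.X[ref_idx].copy(), method="random")


def kmeans_partition(
    db: DescriptorDatabase,
    M: int,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Partition:
    """Partition by k-means; references are the final centroids.

    Lloyd iterations run to convergence (centroid shift below ``tol`` or
    ``max_iter``); the best of ``n_restarts`` seeded, distance-weighted
    initializations by within-cluster sum of squares is kept.  Final
    membership is recomputed against the returned centroids so the
    nearest-reference invariant and deterministic tie-breaking hold exactly.
    """
    if not 1 <= M <= len(db):
        raise ParameterError(f"M must be in [1, {len(db)}], got {M}")
    km = KMeans(
        n_clusters=M,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed % (2**31),
        algorithm="lloyd",
    ).fit(db.X)
    return _assemble(db, km.cluster_centers_, method="kmeans")


def balance_profile(partition: Partition) -> list[int]:
    """Cluster sizes in descending order; sums to the database size."""
    return sorted((c.member_idx.size for c in partition.clusters), reverse=True)


def within_cluster_ss(db: DescriptorDatabase, partition: Partition) -> float:
    """Within-cluster sum of squared distances to the reference points."""
    total = 0.0
    for c in partition.clusters:
        if c.member_idx.size:
            total += float(((db.X[c.member_idx] - c.center) ** 2).sum())
    return total
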