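"""Search results with instrumentation.

Every search routine reports, besides the ordered hits, how many
full-dimension distance computations it performed.  The ratio of that count
to the database size (the evaluation ratio) is the hardware-independent cost
measure used throughout the benchmarks; a linear scan has ratio exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SearchResult:
    """Ordered ``(id, distance)`` hits plus distance-evaluation accounting."""

    ids: list[str]
    distances: np.ndarray
    n_distance_evaluations: int
    n_db: int
    #: Keys in pop order for best-first searches (diagnostic; non-decreasing).
    popped_keys: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.distances = np.asarray(self.distances, dtype=float)

    @property
    def hits(self) -> list[tuple[str, float]]:
        return list(zip(self.ids, self.distances.tolist()))

    def __len__(self) -> int:
        return len(self.ids)


def order_by_distance(dists: np.ndarray, ids: list[str] | np.ndarray) -> np.ndarray:
    """Indices sorting ascending by distance, ties broken by lower id."""
    ids = np.asarray(ids, dtype=str)
    return np.lexsort((ids, np.asarray(dists, dtype=float)))
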