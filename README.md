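# zdsearch

Exact similarity search for protein surface shapes represented as **3D
Zernike descriptors (3DZD)**.

Comparing protein structures by aligning atoms is far too slow for querying
databases of 10<sup>5</sup>+ chains. A practical alternative represents each
voxelized molecular surface as a compact rotation-invariant vector and ranks
structures by Euclidean distance between vectors. Even then, a linear scan
over every descriptor is the bottleneck once many queries arrive, so this
package puts two *exact* metric indexes in front of the database and adds
the reduced-dimension two-stage searches that exploit how shape information
is ordered inside a 3DZD.

## What is inside

**Descriptors.** A shape function `f(x)` on the unit ball is expanded in the
Zernike–Canterakis basis `Z_nlm(r, θ, φ) = R_nl(r) Y_lm(θ, φ)` with
`0 ≤ l ≤ n`, `n − l` even, `|m| ≤ l`. Moments

    Ω_nlm = 3/(4π) ∫_{|x|≤1} f(x) conj(Z_nlm)(x) dx

are collapsed into rotation-invariant norms `F_nl = sqrt(Σ_m |Ω_nlm|²)`,
giving 121 non-negative invariants at the default order `n ≤ 20`. Leading
invariants encode global shape; trailing ones encode fine surface detail.

**iDistance.** The database is partitioned into `M` clusters with reference
points `O_i`; each point gets the scalar key `y = i·C + dist(p, O_i)` in one
sorted sequence. k-NN queries grow a radius `r` by `Δr` per iteration and
scan only the key sub-intervals that the query ball can reach; threshold
(θ) queries do a single fixed-radius pass. Results are exact.

**iKernel.** Each cluster's members are grouped into concentric rings of
`g` points. A best-first priority queue seeded with the outermost rings pops
entries by a minimal-possible-distance lower bound; popped rings evaluate
their members and admit the next ring inward, popped points are guaranteed
results. Exact for both top-k and θ queries.

**Extended (reduced-dimension) search.** An index built on only the first
`m = 60` invariants retrieves `k × 10` candidates that are re-ranked by full
121-dim distance (approximate but high-coverage for top-k; provably exact
for θ-queries, since a coordinate-prefix distance never exceeds the full
distance).

Everything is instrumented with the **evaluation ratio** — the fraction of
database points whose full distance to the query is computed (1.0 for a
linear scan) — the hardware-independent cost measure used in the benchmark
harness, alongside brute-force oracles and a synthetic descriptor generator
that emulates 3DZD statistics.

## Worked example

```sh
# 1000 synthetic 121-dim descriptors, an iKernel index, a top-5 query
zdsearch synth -n 1000 --dim 121 -o db.tsv --seed 7
zdsearch build-index db.tsv --backend ikernel -M 32 --g 50 -o db.idx
zdsearch query db.idx --query-file q.tsv --k 5
```

where `q.tsv` holds one descriptor row (here: row `s000123` of the
database). Output:

```
1	s000123	0
2	s000352	0.337773992826
3	s000353	0.345449334206
4	s000621	0.359377281084
5	s000947	0.40923122093
```

Rank, structure id, Euclidean distance between descriptors; the query is a
database member, so it comes back first at distance 0. The same thing in
Python, with cost instrumentation:

```python
from zdsearch import (generate_synthetic_descriptors, kmeans_partition,
                      build_ikernel, knn_ikernel, evaluation_ratio)

db = generate_synthetic_descriptors(1000, seed=7)
index = build_ikernel(db, kmeans_partition(db, M=32, seed=0), g=50)
res = knn_ikernel(index, db.X[123], k=5)
res.hits[:2]            # [('s000123', 0.0), ('s000352', 0.3377739928...)]
evaluation_ratio(res)   # 0.848 -- fraction of the database actually touched
```

Descriptors can also be computed from voxel grids (text rasters, see
`zdsearch.io`): `compute_descriptor(grid, order=20)` returns the 121
invariants of a shape, identical (to ~1e-13 relative) for any rotation of
the input.

## Layout

| module | contents |
| --- | --- |
| `zdsearch.grid`, `zdsearch.zernike` | voxel grids, normalization, Zernike moments and invariants |
| `zdsearch.partitioning` | descriptor databases, Euclidean metric, random/k-means reference points |
| `zdsearch.idistance` | key index, exact k-NN and θ-range search |
| `zdsearch.ikernel` | ring index, best-first exact search |
| `zdsearch.extended` | prefix index + full-distance re-ranking, coverage metric |
| `zdsearch.bench` | oracles, evaluation ratio, synthetic generators, benchmark harness |
| `zdsearch.io`, `zdsearch.cli` | TSV/raster formats, index persistence, command line |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
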