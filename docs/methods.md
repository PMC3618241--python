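# Methods

This note records the models, numerical conventions, and design decisions
behind `zdsearch`, in the spirit of a package reference manual: what is
computed, under which assumptions, and what the tests do and do not show.

## 1. 3D Zernike descriptors

### Model

A voxel grid carries a real scalar field `f` (for molecular surfaces, an
occupancy indicator) on an `Nx × Ny × Nz` lattice. Before moment
computation the continuous frame is translated to the support's center of
mass and scaled uniformly so the farthest nonzero voxel sits at radius
**0.7** (`margin`, configurable). The margin keeps the support away from
the unit-sphere boundary, where a midpoint Riemann sum would otherwise
truncate boundary voxels — standard practice for grid-sampled moments.

The basis is `Z_nlm = sqrt(3) · R_nl(r) · Y_lm(θ, φ)` with orthonormal
complex spherical harmonics (`scipy.special.sph_harm_y`) and Canterakis
radial polynomials

    R_nl(r) = Σ_{ν=0}^{k} q_{klν} r^{2ν+l},   k = (n−l)/2,
    q_{klν} = (−1)^k/2^{2k} · sqrt((2l+4k+3)/3) · C(2k,k)
              · (−1)^ν C(k,ν) C(2(k+l+ν)+1, 2k) / C(k+l+ν, k).

With the `sqrt(3)` factor the basis is orthonormal in plain L² over the
unit ball; the unit test verifies the Gram matrix of all order ≤ 4
functions on a 48³ midpoint quadrature to within 0.02. Moments are

    Ω_nlm = 3/(4π) Σ_v f(x_v) conj(Z_nlm)(x_v) ΔV

over voxel centers with |x| ≤ 1 (a midpoint rule; no higher-order
quadrature — accuracy is asserted through invariance properties, not
absolute values). Only `m ≥ 0` is computed; `m < 0` follows from conjugate
symmetry of the harmonics for real `f`.

The descriptor is `F_nl = sqrt(Σ_m |Ω_nlm|²)`, ordered lexicographically in
`(n, l)` — 121 non-negative components at the default order 20. The
per-(n, l) Euclidean norm over `m` is the only contraction of the moments
that is invariant under rotations of the input (each fixed-(n, l) block of
moments transforms unitarily under SO(3)); a plain sum of squared complex
moments would be neither real nor invariant, so the norm convention is used
throughout. Because the overall basis normalization differs between
conventions in the descriptor literature, tests assert *properties*
(rotation invariance under the 24 exact lattice rotations to 1e-6 relative,
homogeneity under scaling of `f`, suppression of all `l > 0` components for
a centered ball) rather than absolute invariant values. Observed behavior
is far inside these tolerances (~1e-13 rotation deviation; `l > 0` leakage
for a voxelized ball ≈ 1% of `F_00`, which is lattice-anisotropy
discretization error, shrinking with grid resolution).

Degenerate inputs: an all-zero grid cannot be normalized
(`EmptySupportError`); a single-voxel support maps to the origin with unit
scale; `f ≡ 0` yields all-zero moments and invariants.

## 2. Partitioning

Both indexes consume the same structure: `M` clusters with reference points
`O_i` and radii `dist_max_i = max_{p∈i} dist(p, O_i)`, under the Euclidean
metric (the metric of the linear-scan baseline; not user-pluggable in v1).

* `random_partition`: `M` database points sampled uniformly (seeded),
  everything assigned to its nearest reference.
* `kmeans_partition`: Lloyd's algorithm via scikit-learn (`k-means++`
  distance-weighted seeded initialization, best of `n_restarts = 3` by
  within-cluster sum of squares, `tol = 1e-4`, `max_iter = 300`); empty
  clusters are relocated internally by the library. Final membership is
  recomputed against the returned centroids so the nearest-reference
  invariant holds exactly, with ties broken toward the lower cluster index
  for determinism.

k-means produces markedly better balanced clusters than random references
(asserted over 10 seeds via the max/min cluster-size ratio), which is what
keeps per-cluster scan costs predictable. Selection across restarts is by
WCSS only; selecting by downstream search performance is a possible
refinement deliberately left out of v1. Cluster-count presets 121/242/498/866
(dimension, twice the dimension, and two protein-taxonomy counts) are the
defaults a full-scale descriptor database would use; the desk-scale
benchmarks here use `M = 64` to match their smaller databases.

## 3. iDistance

Key: `y = i·C + dist(p, O_i)`; `C = 4` by default, validated at build time
against every `dist_max_i` (the build refuses overlapping key intervals and
names the violating cluster). The synthetic generator keeps all pairwise
distances well below 4, the same regime the normalized descriptors of real
databases occupy. Keys live in a single sorted array per cluster with
binary search — the disk-era B+-tree has the identical contract in memory
and bit-equal results.

Top-k search: radius starts at `Δr` (the iteration rule "grow by Δr" fixes
the natural starting value) and grows by `Δr = 0.2` per round. A cluster is
scanned when `dist(q, O_i) − r ≤ dist_max_i`; within it only the key
interval `[max(0, d_i − r), min(dist_max_i, d_i + r)]` is touched, and
partially scanned clusters resume from their visited frontier, so no point
is ever evaluated twice (hence `n_distance_evaluations ≤ n` always).
Termination when the k-th best distance ≤ r is exact by the reverse
triangle inequality. Ties at the k-th distance go to the lower id.

θ-search is a single pass with fixed radius θ, keeping strictly
`dist < θ` (the strict inequality is a fixed, flag-free choice).

`Δr` sensitivity: the stopping radius is `Δr·ceil(d_k/Δr)`, which is
monotone only along divisor chains of Δr values; on the halving ladder
{0.8, 0.4, 0.2, 0.1} a smaller Δr never evaluates more points (asserted),
while arbitrary Δr pairs can invert for individual queries.

## 4. iKernel

Each cluster's members, sorted by centroid distance, are grouped into rings
of `g = 50` points starting from the **outermost** point, so all full rings
sit outside and only the innermost ring may be short — the search seeds
from outside, so full rings are where the seeding happens. Ring radii are
the min/max member distances (the tightest annulus bounds available from
stored data).

The annulus bound exposed as `mpd(q, ring)` is `d − outer` beyond the ring,
`inner − d` inside it, 0 within (with `d = dist(q, centroid)`); it lower
bounds the distance to every member of that ring.

Search is best-first: the queue is seeded with each cluster's outermost
ring; popping a ring evaluates its `g` members (pushed at true distance)
and admits the next ring inward; popping a point emits it. **Queue keys for
ring entries are `max(0, d − outer)`**, not the full annulus bound: a ring
entry is the *gateway* to everything centroid-ward of it, and
`max(0, d − outer)` is the valid lower bound for that whole remainder. For
a query outside the cluster the two coincide; for a query inside, the
`inner − d` branch would over-estimate and could starve a near interior
point behind a far entry, breaking exactness. The gateway form also makes
the popped-key sequence non-decreasing — asserted on every search in the
tests — which is exactly the property that makes emitted points exact and
lets the θ-variant terminate the moment a popped key reaches θ. Tie-breaks
(rings before points at equal key, then lower (cluster, ring) / id) keep
traces deterministic.

## 5. Extended (reduced-dimension) searches

`build_reduced` indexes exact coordinate *prefixes* (first `m` components;
`m = 60` by default — half of 121, rounded as the global-shape half of the
descriptor). Since a prefix distance never exceeds the full distance:

* **top-k**: retrieve `k × 10` candidates by prefix distance, re-rank by
  full distance, keep `k`. Exact within its candidate set; overall coverage
  of the true top-k is below 1 in general and rises with `m`.
* **θ-range**: prefix range query with the same θ, then filter candidates
  by full distance — *exact*, because every true θ-neighbor survives
  stage 1 by the lower bound.

Evaluation accounting: an m-dim and a full-dim distance each count as one
access; at `m = dim` the stage-2 re-evaluation is skipped (the prefix
distance already is the full distance), so counts coincide with the basic
backend. The cheaper per-access cost of m-dim arithmetic shows up in the
benchmark's wall-clock column instead.

## 6. Synthetic data

`generate_synthetic_descriptors` emulates three statistical features of
real 3DZD databases (values non-negative, variance decaying from leading to
trailing coordinates, family/cluster structure):

* blob centers with per-coordinate scale `0.35 · decay^c`
  (`decay = 0.95`): the family structure lives almost entirely in the
  leading, global-shape coordinates;
* flat within-blob Gaussian noise (`blob_spread = 0.035`): fine variation
  spread across the whole vector;
* sparse **detail spikes** — `Poisson(1)` components per point of bounded
  magnitude `0.3 · U(0.5, 1.5)` at random trailing-half coordinates — the
  occasional large high-order invariant a distinctive surface feature
  produces. Spikes matter: they inflate full-space cluster radii (a max
  statistic) far more than typical neighbor distances, which is the
  mechanism that makes reduced-dimension indexing cheaper than full-space
  indexing for θ-queries. Without them, prefix and full-space indexes cost
  the same and the reduced-index advantage disappears.

Defaults (`n_blobs = 64`) define the efficiency benchmark
(n = 10,000, M = 64, 100 queries drawn from the database, θ calibrated so
threshold results average ~k = 25 hits — `calibrate_theta` returns the
median k-th-neighbor distance over sampled queries). The separate
**coverage benchmark** (`COVERAGE_BENCH`: n = 5,000, 8 strongly overlapping
blobs, spread 0.06) emulates the continuum regime where a query's
neighborhood exceeds the k × 10 candidate budget — the regime in which
extended top-k is genuinely approximate; its mean top-25 coverage rises
from ~74% at m = 12 through ~96% at m = 60 to exactly 100% at m = 121,
matching the ~95% half-dimension coverage reported for real descriptor
databases. Both configurations keep every pairwise distance below the key
constant C = 4.

What the generator does **not** model: real invariant marginals (gamma-like,
strictly positive), inter-coordinate correlations from the moment
hierarchy, or database-scale effects (158k+ chains, M = 866). Passing
benchmarks therefore demonstrate algorithmic correctness and the
qualitative cost orderings, not absolute evaluation ratios of any real
database.

## 7. Benchmarks and problem sizes

All searches report `n_distance_evaluations`; the evaluation ratio (count
over database size) is the hardware-independent cost measure, exactly 1 for
linear scans. Wall-clock means are reported for context and never asserted.
The harness runs every method on a shared without-replacement query sample
and cross-checks every exact method's hit list per query.

Reference problem sizes used by the test suite and `scripts/acceptance.py`:
exactness gates at n ∈ {500, 5,000} over three seeds with
k ∈ {1, 25, 100} and θ ∈ {0.5, 1, 2}; the efficiency study at n = 10,000
with 100 queries; descriptor symmetry checks at order 20 on 64³ (tests) and
48³ (script) grids — sizes chosen to exercise every pruning regime while a
full run stays in the minutes range on a single CPU.

## 8. Known limitations

* Indexes are in-memory; no disk-resident paging or concurrent-query
  simulation.
* The Zernike pipeline starts from voxel grids; surface generation from
  atomic coordinates (and PDB/mmCIF parsing) is out of scope.
* k-means restart selection by WCSS, not by downstream search cost.
* `C` is validated, not auto-tuned; data whose cluster radii exceed 4
  requires passing a larger `C` explicitly.
* Extended top-k is approximate by design; use the θ-variants when
  exactness of the reduced index is required.
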