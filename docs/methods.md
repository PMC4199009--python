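# Methods

## Model

The interpolator treats a day index as a third spatial coordinate. A scale
factor *c* with units degrees/day converts the time axis so that the scaled
study period spans the mean of the longitude and latitude ranges:

    c = ((x_max − x_min) + (y_max − y_min)) / 2 / (n_days − 1)

The denominator is the *span* of the day index (n_days − 1), which for a
365-day year is 364; a leap year yields 365, and multi-year input a
correspondingly larger span. The underlying assumption is that space and
time are equally important for the phenomenon: a separation of one day
should matter as much as a spatial separation of *c* degrees. This is a
modeling choice, not an estimated quantity; `AxisScales` exposes the three
axis coefficients (cx, cy, ct) individually so other calibrations can be
substituted, with cx = cy = 1 as the default.

Given scaled coordinates, the prediction at a query point is inverse
distance weighting over its N nearest measurements:

    w = Σᵢ λᵢ wᵢ ,   λᵢ = dᵢ⁻ᵖ / Σₖ dₖ⁻ᵖ

Weights are a convex combination — they are non-negative and sum to one —
so every prediction lies between the minimum and maximum neighbor value.
Larger exponents p concentrate weight on the closest neighbors; as p → ∞
the prediction tends to the single nearest neighbor's value.

Coordinates are planar decimal degrees throughout; no great-circle or
projection correction is applied. At continental scale a degree of
longitude shrinks toward the poles, so east–west distances are
systematically overweighted at high latitudes. This is a known limitation
accepted for fidelity to the method as practiced.

### Original vs. improved variant

The original variant always uses all N nearest neighbors, however distant.
The improved variant discards candidates whose full scaled spatiotemporal
distance exceeds `max_distance` or whose day offset exceeds
`max_time_diff`; the surviving subset (possibly empty) is weighted as
usual. `max_distance` is interpreted in scaled extension-space units —
the same metric the neighbor search itself uses — while `max_time_diff`
is interpreted in raw days, since its purpose is calendar reasoning
("don't let December inform April"). An empty neighborhood produces an
explicitly missing prediction (`value = None`, `neighbors_used = 0`);
missing predictions are never silently dropped, and cross-validation counts
them as skips rather than scoring them as infinite error.

### Zero distances

The IDW weight is undefined at dᵢ = 0. When one or more neighbors coincide
exactly with the query point, those zero-distance neighbors take over: the
prediction is their mean and they share the unit weight equally. This keeps
the interpolator exact at measured locations (the defining property of IDW)
while remaining well-defined under co-located duplicate records, which are
kept as independent samples at ingest rather than averaged.

## Nearest-neighbor search

The k-d tree is built once per dataset by recursive median splits cycling
the axes (x, y, scaled t, x, …). At each level the *lower* median along the
current axis becomes the node and keys equal to the median go to the left
subtree, making construction deterministic under duplicates. Points are
stored at every node, not only leaves.

The multi-neighbor search carries a bounded priority queue of capacity k.
A subtree on the far side of a splitting plane is descended only while the
queue is not yet full or the plane touches the candidate hypersphere of
radius r (the worst retained distance).

Two tie-handling rules make the search canonical. Each node remembers its
index in the build input, and the queue totally orders candidates by
(distance, input index): a full queue accepts an incoming candidate exactly
when its pair precedes the current worst, and the plane test uses
|qᵢ − aᵢ| ≤ r so an equal-distance, earlier-index candidate beyond the
plane is never pruned away. The result is the unique k smallest
(distance, input index) pairs regardless of tree shape. This matters in
practice, not just in pathological inputs: a station's records on days
t − Δ and t + Δ are *exactly* equidistant from its day-t record (distance
c·Δ), so boundary ties occur in every daily dataset, and leave-one-out
neighborhoods computed on a full tree must agree with those computed on a
rebuilt tree for the cross-validation identities below to hold. A plain
`NeighborQueue.insert` without an explicit order key falls back to
insertion order, i.e. an incoming candidate tied with the worst entry is
rejected.

## Cross-validation

MARE and RMSPE are relative errors, mean(|I−O|/O) and
sqrt(mean(((O−I)/O)²))·100; both are invariant to rescaling all values.
Records observed at exactly zero cannot be scored by either and are
excluded with a counted skip, as are missing predictions.

LOOCV predicts each record from all others. It is implemented with a single
tree: each query requests N+1 neighbors and removes the held-out record
(distance zero) — or, when an exact co-located duplicate displaced it, the
surplus worst candidate — which under the canonical tie order yields
exactly the N nearest other records. Only the held-out record itself is
excluded; other records of the same site remain eligible.

k-fold CV shuffles records with a seeded generator into folds whose sizes
differ by at most one and predicts each fold from a tree over the rest.
Hold-out pairs are pooled before computing the statistics, so k-fold with
k = n reproduces LOOCV pair for pair (this identity is tested). Averaging
the per-fold statistics instead is available via `pooling="per_fold"` for
comparison with conventions that weight folds equally.

The grid search evaluates every (N, p) combination, by default
N ∈ {3,4,5,6,7} × p ∈ {1, 1.5, …, 5} (45 configurations), and exposes
rankings by minimum MARE and minimum RMSPE separately, since the two can
disagree.

## Parallel engine

The work unit is one target location across all days of the period; tasks
are mutually independent and share the immutable station tree, so execution
is embarrassingly parallel over a shared queue of tasks. Results are
reassembled by task index, making output identical — byte-for-byte once
serialized — for any worker count; the default pool size is the number of
available processors. Workers are threads: the contract is determinism and
exactly-once execution, not a particular concurrency mechanism.

## Synthetic data generator

The generator emulates the structure of a daily monitoring dataset: point
stations over the continental-US bounding box (the default bbox reproduces
c ≈ 0.1086), one value per station per day. The ground-truth field is

    f(x, y, t) = max(0, baseline + A_s·sin(2πt/n_days) + Σⱼ Aⱼ·exp(−|r − cⱼ(t)|²/(2wⱼ²)))

— a baseline (default 8 µg/m³, a typical continental background), a
seasonal sinusoid (default amplitude 3 µg/m³), and traveling Gaussian
plumes (two by default, ~14–20 µg/m³ peaks, 6–8° widths, drifting a few
hundredths of a degree per day) that exercise the temporal axis.
Observations add Gaussian noise (default sd 1 µg/m³) and clamp at zero.
Station placement is uniform, or concentrated around five random cluster
centers as the `clustering` parameter approaches 1 — leaving the sparse
regions that motivate the restricted neighborhood. All generation is
deterministic given the seed.

What the generator does *not* emulate: real atmospheric dispersion,
station-specific biases or gaps in the daily record, heavy-tailed
concentration distributions, or the true spatial layout of a monitoring
network. Tests passing on this field demonstrate correctness of the
machinery and the qualitative behavior of the methods, not real-world error
magnitudes.

The decoy helper plants a handful of stations far outside the bounding box
(≥ 5° beyond an edge), each reporting a single grossly aberrant value on
one day. The single-day design is deliberate: a decoy present on *all*
days would be predicted almost perfectly from its own adjacent-day records
(the scaled time axis makes same-site temporal neighbors the closest
candidates) and would perturb neither variant. An isolated single-day
reading, by contrast, is exactly the situation the restricted neighborhood
is for: the fixed-N method scores it against far-away stations with large
relative error, while the improved method declines to predict it.

## Problem sizes

Tests and the acceptance script run at desk scale by design: synthetic
networks of 25–400 stations over 5–30 days, target grids up to 10 × 5, and
oracle comparisons over hundreds of points and queries. These sizes
exercise every code path (including tree depths where pruning matters)
while keeping the full suite fast; the engine's workload arithmetic is
checked at the realistic counts (3109 and 207,630 targets × 365 days)
without executing those predictions.

## Known limitations

- Planar-degree geometry (see above).
- IDW cannot extrapolate beyond the range of its neighbors' values and
  inherits sensitivity to clustered sampling; no declustering is applied.
- The scale factor ties the time axis to the *extent* of the data, so
  adding a day to the record changes every scaled coordinate slightly.
- Cross-validation here is record-level; site-level (spatially blocked)
  validation, variance estimates, and comparisons against geostatistical
  interpolators are out of scope.
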