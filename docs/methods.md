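# Methods

## The validity index

DBCV scores a hard partition of $n$ points in $\mathbb{R}^d$ by density.
The all-points-core-distance (APCD) of a point is the inverse-power
generalized mean (exponent $-d$) of its distances to every other member of
its cluster; it is small in dense neighbourhoods and, as $d$ grows, is
dominated by the nearest cluster-mates. Mutual reachability distance (MRD)
replaces the Euclidean metric by
$\max(\mathrm{APCD}_i, \mathrm{APCD}_j, d_{ij})$, flattening distances
inside dense regions. Density sparseness (DSC) is the largest MRD edge of a
cluster's minimum spanning tree; density separation (DSPC) is the smallest
cross-cluster MRD; cluster validity is their normalized gap; and the index
is the cluster-size-weighted sum of validities, with the weight denominator
counting *all* points. Noise therefore shrinks the index toward zero
without changing any per-cluster validity — noisy solutions are penalized
in magnitude, not direction.

### The two DSC/DSPC conventions

The printed definitions ("max over MST edges", "min over all cross pairs")
are the package defaults. They have one consequence worth knowing: every
point's APCD appears on at least one incident MST edge, so the literal DSC
is bounded below by the cluster's *maximum* APCD. One locally sparse point
inflates DSC for the whole cluster, and in higher dimensions (where APCD
concentrates on nearest-neighbour distances) this systematically depresses
the index for genuinely good partitions. The original 2014 convention —
DSC restricted to MST edges between internal nodes (degree ≥ 2, leaf edges
excluded, with a fallback to all edges when none exist), DSPC restricted to
internal nodes — is what the published reference implementations compute,
and it is markedly less sensitive to boundary points. Both are exposed
(`dsc_mode`, `dspc_mode`); analyses that compare numbers against reference
packages should use `"internal"`. On the shifting-rings benchmark below the
literal reading averages ≈ 0.3 over the two-cluster datasets while the
internal convention averages ≈ 0.5; the acceptance script reports the
internal-convention value, as that is the convention under which the
benchmark level was established.

### Numerical choices and degenerate inputs

- Coincident cluster-mates give a $(1/0)^d$ term; infinity-aware arithmetic
  yields the limiting APCD of 0 rather than an error, preserving continuity
  under perturbation.
- Singleton clusters have no APCD ($|C_i|-1 = 0$). The default is a hard
  error (silent coercion hides upstream clustering failures); passing
  `singletons="noise"` demotes them. The *registered* metric plugins use the
  tolerant policy, because fragmented clusterer outputs inside a sweep are
  data, not bugs.
- The validity denominator is guarded: if both DSC and DSPC are below
  1e-12 (all points of two clusters coincide), an undefined-validity error
  is raised.
- MSTs are built by scipy's deterministic scan (fixed row/column edge
  order). DSC depends only on edge weights, for which all MSTs of a graph
  agree, so tie-breaking cannot change results; the fixed order matters only
  for which edges the internal-node bookkeeping sees, and is reproducible.
- Fewer than two clusters after noise handling is an error: separation is a
  minimum over an empty set.
- Distances are Euclidean only.

## Shape generators

Each family takes an explicit integer seed, is bit-for-bit reproducible,
and carries ground-truth memberships and provenance metadata.

- **half_moons**: 1,000 points on two interlocking crescents
  (scikit-learn's moons geometry), Gaussian jitter
  $\sigma \in \{0.0, 0.056, \dots, 0.5\}$ (10 levels).
- **shifting_circles**: 500 points uniform in angle on an outer ring of
  radius 1.5 plus 500 on an inner ring of radius 0.5 whose centre sits at
  $(0.2k, 0)$ for level $k$; exact circles by default, optional Gaussian
  radial jitter. The rings pass from nested-and-separated (gap 1.0) through
  touching ($k = 5$) to overlapping.
- **sparse_circles**: 1,000 points on two concentric rings (inner/outer
  radius ratio 0.5 by default, configurable — the ratio is a free choice
  matching visibly separated rings), jitter $\sigma = 0.05 + 0.0555k$.
- **tulip**: a packaged 600-point synthetic crescent base cloud
  (deterministic parametric arcs, normalized to $[0,1]^2$; a stand-in
  constructed because the historical base coordinates ship only in a
  proprietary format), augmented with 400 points resampled from the base
  plus jitter on the half-moons schedule and wrapped back into $[0,1]$ by
  modulo. Output is base followed by augmentation; at zero jitter the
  augmented points duplicate base points exactly (exact 1.0 coordinates are
  kept at 1.0 rather than wrapped to 0).

**Synthetic patient tables** (`gen_synthetic_ehr`): a mixed-type stand-in
for small clinical registries. Defaults: 168 rows and 13 columns (7 numeric,
2 ordinal, 2 categorical, 2 binary) — the shape of a small oncology cohort —
with $k = 3$ balanced planted groups. Numeric columns are unit-variance
Gaussians around group centres scaled so the minimum pairwise centre
distance equals `separation` (default 4; the tuned-recovery analyses use 6,
"strong structure"). Ordinal columns discretize group-shifted latent
normals at pooled equal-frequency cut points (4 levels); categorical and
binary columns use softmax/logistic group-dependent probabilities that
collapse to uniform at separation 0, so zero separation genuinely carries
no signal. Missing cells are planted uniformly at `missing_rate`.

What this generator does *not* emulate: correlated features, informative
missingness, heavy-tailed laboratory values, measurement batch effects, and
overlapping diagnoses. Passing protocol tests on these tables shows the
*machinery* behaves as designed under known structure; it does not certify
performance on real clinical records.

## Clustering adapters

DBSCAN, HDBSCAN, and MeanShift run through scikit-learn behind a uniform
adapter that canonicalizes labels (noise −1, clusters renumbered in order
of first appearance). Published defaults: DBSCAN eps 0.5 / minPts 5;
HDBSCAN min cluster size 5 / selection epsilon 0; MeanShift bandwidth
estimated at fit time (quantile 0.3 — the estimator's quantile is otherwise
unspecified, recorded here as the package's convention). Random draws:
MeanShift bandwidth ~ U(0.1, 5); DBSCAN eps ∈ [0.1, 1.5], minPts ∈ {3..15};
HDBSCAN min cluster size ∈ {5..20}, epsilon ∈ [0, 1] — envelopes chosen to
cover the draws the trend protocol realizes, all configurable.

Mixed-type preprocessing: numeric → median-impute + standardize; ordinal →
integer ranks + standardize; binary → {0, 1} with mode imputation;
categorical → mode-impute + one-hot. Zero-variance columns are dropped with
a warning. Gower-style distances are out of scope by design; standardize +
one-hot is the least surprising convention when none is prescribed.

## Protocols

**Noise sweeps.** For one family and one clusterer configuration, generate
all 10 levels, cluster, and evaluate every requested registered metric; any
metric failure is a per-cell N/A. The trajectory statistic is the number of
strictly decreasing adjacent numeric pairs (N/A entries break pairs), and a
series is *consistent* when strict decreases form a strict majority of its
numeric pairs. A series constant at every level is inconsistent:
invariance under degradation means insensitivity. "Predominantly decrease"
has no printed threshold, so the majority rule is this package's
operationalization and the raw counts are always reported alongside.

The sweep's DBSCAN settings are per-family: eps 0.1 (half moons), 0.2
(shifting circles), 0.1 (sparse circles), 0.05 (tulip), all with minimal
points 10. Rationale: eps must sit above the within-cluster sampling
spacing and below the zero-degradation inter-cluster gap, which differs per
geometry (the tulip cloud lives in the unit square); minPts 10 ≈ 2 ln n for
the 1,000-point clouds keeps sparse jitter from seeding spurious clusters.
The generic published default (eps 0.5) would merge the two half-moon arcs
(curve gap exactly 0.5) at every level and leave the whole sweep N/A.

**ARI-trend consistency.** Cluster one numeric matrix with all three
methods under setting A and setting B (canonically: random draws vs
defaults; the synthetic-table analyses use data-driven *tuned* settings —
DBSCAN eps at 1.5× the median 5th-nearest-neighbour distance, HDBSCAN's
default minimum cluster size, the quantile bandwidth estimate — against
*degraded* ones that halve the density scales and inflate the minimum
cluster size to a quarter of the dataset). The average of the three
pairwise ARIs anchors the direction of change. Per (metric, clusterer):
not-applicable if either metric value is missing; otherwise consistent when
the metric's non-strict direction matches the ARI's strict direction — an
exactly unchanged metric matches either direction, a deliberate rule
mirroring how flat metric rows are scored against a moving ARI. An exactly
zero ARI change raises an explicit error rather than being silently
classified. Summaries count verdicts per metric, with the consistency
percentage computed over all trials including not-applicable ones.

The native ARI is a contingency-table pair-counting implementation (noise
treated as an ordinary group, with an option to exclude noise points);
scikit-learn's ARI serves as an independent cross-check in the tests, never
as the implementation.

## Problem sizes

The shipped analyses use the generators' study conditions throughout:
1,000-point shape clouds across 10 levels, 5 sweep replicates, and 20
replicates of the 168 × 13 patient table for the trend protocol. The
exhaustive ARI validation enumerates all partition pairs through n = 6
(≈ 44,000 pairs) and large seeded samples at n = 7 and 8, where full
enumeration (17.1M pairs) would add nothing but time.

## Known limitations

- The index is $O(n^2)$ in memory and time; no approximate or streaming
  variant is provided.
- Euclidean geometry only; mixed-type data must pass through the encoding
  above, and one-hot distances are a modelling choice, not ground truth.
- The tulip base cloud is a synthetic reconstruction, not the historical
  coordinates; only the augmentation protocol is reproduced faithfully.
- Consistency verdicts compare directions between exactly two settings; they
  say nothing about the magnitude of metric changes.
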