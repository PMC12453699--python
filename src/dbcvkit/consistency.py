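"""Reliability protocols for internal cluster-validity metrics.

Two complementary checks of whether a validity index tracks real clustering
quality:

* **Noise-degradation sweep** (:func:`run_noise_sweep`): generate one shape
  family at its 10 degradation levels, cluster each level, and record every
  registered metric's trajectory.  A reliable metric should *predominantly
  decrease* as degradation grows; :func:`decreasing_pair_count` counts the
  strictly decreasing adjacent pairs and :func:`classify_noise_trend` turns
  that into a consistent/inconsistent call (a series constant at every level
  is inconsistent — invariance means insensitivity).

* **ARI-trend consistency** (:func:`run_trend_protocol`): cluster one dataset
  with DBSCAN, HDBSCAN, and MeanShift under two hyperparameter settings
  (canonically: randomly drawn vs default).  The average pairwise adjusted
  Rand index among the three labelings measures how much the solutions agree
  under each setting; a metric is *consistent* for a clusterer when its
  change between the two settings points the same way as the ARI change.

External validity indices participate through a plugin registry
(:func:`register_metric`): a plugin is any callable ``fn(points, labels) ->
float`` that may raise on inputs it cannot score; failures become
not-applicable records, never crashes.  The native DBCV index is always
registered; a Silhouette adapter (scikit-learn, noise points excluded) is
included as a convex-geometry reference plugin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import backends
from .dbcv import NOISE_LABEL, dbcv_score
from .exceptions import DbcvError, UndefinedTrendError
from .generators import N_LEVELS, generate

NOT_APPLICABLE = None

__all__ = [
    "MetricSeries",
    "SweepResult",
    "TrendRecord",
    "ConsistencySummary",
    "register_metric",
    "registered_metrics",
    "evaluate_metric",
    "decreasing_pair_count",
    "classify_noise_trend",
    "adjusted_rand_index",
    "average_pairwise_ari",
    "trend_verdict",
    "run_noise_sweep",
    "run_trend_protocol",
    "tuned_degraded_configs",
    "consistency_summary",
]


# ---------------------------------------------------------------------------
# metric plugin registry

_METRICS: dict[str, Callable] = {}


def register_metric(name: str, fn: Callable) -> None:
    """Register a validity metric plugin ``fn(points, labels) -> float``."""
    if not callable(fn):
        raise DbcvError("metric plugin must be callable")
    _METRICS[str(name)] = fn


def registered_metrics() -> tuple[str, ...]:
    return tuple(_METRICS)


def evaluate_metric(name: str, points, labels):
    """Evaluate a registered metric; any exception becomes not-applicable."""
    if name not in _METRICS:
        raise DbcvError(f"metric {name!r} is not registered")
    try:
        value = _METRICS[name](points, labels)
    except Exception:
        return NOT_APPLICABLE
    if value is None or not np.isfinite(value):
        return NOT_APPLICABLE
    return float(value)


def _silhouette_plugin(points, labels):
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    mask = labels != NOISE_LABEL
    return silhouette_score(np.asarray(points, dtype=float)[mask], labels[mask])


# Registered plugins demote singleton clusters to noise rather than erroring:
# clusterer outputs inside a sweep legitimately contain singletons, and a
# hard error would turn whole sweeps into N/A columns.  The bare dbcv_score
# function keeps the strict default.
register_metric(
    "dbcv", lambda points, labels: dbcv_score(points, labels, singletons="noise")
)
# The original 2014 convention (internal MST edges for sparseness, internal
# MST nodes for separation) — the convention of the published reference
# implementations; exposed as its own registered metric.
register_metric(
    "dbcv_original",
    lambda points, labels: dbcv_score(
        points, labels, singletons="noise", dsc_mode="internal", dspc_mode="internal"
    ),
)
register_metric("silhouette", _silhouette_plugin)


# ---------------------------------------------------------------------------
# series statistics

@dataclass(frozen=True)
class MetricSeries:
    """One metric's trajectory over a degradation schedule (None = N/A)."""

    metric_name: str
    values: tuple

    def __len__(self) -> int:
        return len(self.values)


def _numeric_pairs(values: Sequence):
    vals = list(values)
    return [
        (a, b)
        for a, b in zip(vals, vals[1:])
        if a is not None and b is not None
    ]


def decreasing_pair_count(values: Sequence) -> int:
    """Number of adjacent strictly decreasing numeric pairs.

    N/A entries break pairs (neither pair containing one counts); fewer than
    two numeric entries is an error.
    """
    vals = [v for v in values if v is not None]
    if len(vals) < 2:
        raise UndefinedTrendError("need >= 2 numeric entries to count decreases")
    return sum(b < a for a, b in _numeric_pairs(values))


def classify_noise_trend(values: Sequence) -> str:
    """``'consistent'`` iff strict decreases are a strict majority of the
    adjacent numeric pairs; constant or predominantly rising series are
    ``'inconsistent'``."""
    vals = [v for v in values if v is not None]
    if len(vals) < 2:
        raise UndefinedTrendError("need >= 2 numeric entries to classify a trend")
    pairs = _numeric_pairs(values)
    dec = sum(b < a for a, b in pairs)
    return "consistent" if pairs and 2 * dec > len(pairs) else "inconsistent"


# ---------------------------------------------------------------------------
# adjusted Rand index (native pair-counting contingency implementation)

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Computed from the contingency table: with ``n_ij`` the table cells,
    ``a_i``/``b_j`` the marginals and ``N = C(n, 2)``,

    ``ARI = (sum C(n_ij,2) - sum C(a_i,2) sum C(b_j,2)/N)
            / (0.5 [sum C(a_i,2) + sum C(b_j,2)] - sum C(a_i,2) sum C(b_j,2)/N)``.

    1.0 for identical partitions up to relabeling; symmetric; the noise
    sentinel is treated as a regular group (use
    :func:`adjusted_rand_index_no_noise` to exclude noise points).
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape[0] != b.shape[0]:
        raise DbcvError("labelings must have equal length")
    n = a.shape[0]
    if n < 1:
        raise DbcvError("labelings must be non-empty")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return (x * (x - 1) / 2.0).sum()

    sum_ij = comb2(cont)
    sum_a = comb2(cont.sum(axis=1))
    sum_b = comb2(cont.sum(axis=0))
    total = n * (n - 1) / 2.0
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-singletons or single block): identical
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def adjusted_rand_index_no_noise(labels_a, labels_b, noise_label: int = NOISE_LABEL) -> float:
    """ARI restricted to points clustered (non-noise) in *both* labelings."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    mask = (a != noise_label) & (b != noise_label)
    if not mask.any():
        raise DbcvError("no points are clustered in both labelings")
    return adjusted_rand_index(a[mask], b[mask])


def average_pairwise_ari(labels_dbscan, labels_hdbscan, labels_meanshift) -> float:
    """Mean of the three pairwise ARIs among the three labelings."""
    labs = [np.asarray(x).ravel() for x in (labels_dbscan, labels_hdbscan, labels_meanshift)]
    if len({x.shape[0] for x in labs}) != 1:
        raise DbcvError("labelings must have equal length")
    return float(
        np.mean(
            [
                adjusted_rand_index(labs[0], labs[1]),
                adjusted_rand_index(labs[1], labs[2]),
                adjusted_rand_index(labs[2], labs[0]),
            ]
        )
    )


# ---------------------------------------------------------------------------
# trend verdicts

@dataclass(frozen=True)
class TrendRecord:
    """One (metric, clusterer) row of the ARI-trend protocol."""

    metric_name: str
    clusterer: str
    value_random: float | None
    value_default: float | None
    ari_random: float
    ari_default: float
    verdict: str


def trend_verdict(value_random, value_default, ari_random: float, ari_default: float) -> str:
    """Consistency of one metric's change with the ARI change.

    Not-applicable when either metric value is missing.  Otherwise the metric
    is consistent when its non-strict direction matches the strict ARI
    direction (an unchanged metric matches either way, mirroring how flat
    metric rows are scored as agreeing with a falling ARI).
    """
    if value_random is None or value_default is None:
        return "not_applicable"
    d_ari = ari_default - ari_random
    if d_ari == 0:
        raise UndefinedTrendError("ARI change is exactly zero; trend undefined")
    d_metric = value_default - value_random
    ok = (d_metric <= 0 and d_ari < 0) or (d_metric >= 0 and d_ari > 0)
    return "consistent" if ok else "inconsistent"


@dataclass(frozen=True)
class ConsistencySummary:
    """Per-metric verdict counts over all (clusterer x dataset) trials."""

    metric_name: str
    n_consistent: int
    n_inconsistent: int
    n_not_applicable: int

    @property
    def n_trials(self) -> int:
        return self.n_consistent + self.n_inconsistent + self.n_not_applicable

    @property
    def pct_consistent(self) -> float:
        # percent over all trials, applicable or not
        return 100.0 * self.n_consistent / self.n_trials if self.n_trials else 0.0


def consistency_summary(records: Sequence[TrendRecord]) -> list[ConsistencySummary]:
    """Tally verdicts per metric, preserving first-appearance metric order."""
    if not records:
        raise DbcvError("no trend records to summarize")
    order: list[str] = []
    tally: dict[str, dict[str, int]] = {}
    for r in records:
        if r.metric_name not in tally:
            order.append(r.metric_name)
            tally[r.metric_name] = {"consistent": 0, "inconsistent": 0, "not_applicable": 0}
        tally[r.metric_name][r.verdict] += 1
    return [
        ConsistencySummary(
            metric_name=m,
            n_consistent=tally[m]["consistent"],
            n_inconsistent=tally[m]["inconsistent"],
            n_not_applicable=tally[m]["not_applicable"],
        )
        for m in order
    ]


# ---------------------------------------------------------------------------
# protocol runners

@dataclass(frozen=True)
class SweepResult:
    """Noise-degradation sweep output for one (family, clusterer) pair."""

    family: str
    seed: int
    clusterer: backends.ClustererConfig
    levels: tuple
    n_clusters: tuple
    series: dict = field(repr=False)
    decreasing_pairs: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)


#: Per-family DBSCAN configurations for the artificial-shape sweeps.  The
#: published generic default (eps 0.5) merges the two half-moon arcs at every
#: level, so each family gets a scale-appropriate eps — above the
#: within-cluster sampling spacing, below the zero-degradation inter-cluster
#: gap — with minimal points 10 (~2 ln n for the 1,000-point clouds) to keep
#: sparse jitter from seeding spurious clusters.  Override per call.
SWEEP_CLUSTERERS = {
    "half_moons": backends.ClustererConfig("dbscan", {"eps": 0.1, "min_samples": 10}),
    "shifting_circles": backends.ClustererConfig("dbscan", {"eps": 0.2, "min_samples": 10}),
    "sparse_circles": backends.ClustererConfig("dbscan", {"eps": 0.1, "min_samples": 10}),
    "tulip": backends.ClustererConfig("dbscan", {"eps": 0.05, "min_samples": 10}),
}


def run_noise_sweep(
    family: str,
    clusterer: backends.ClustererConfig | None = None,
    metric_names: Sequence[str] = ("dbcv",),
    seed: int = 0,
    **generate_kwargs,
) -> SweepResult:
    """Cluster all 10 degradation levels of ``family`` and score every metric.

    Metric failures (e.g. a single cluster found) are recorded as N/A for
    that cell; nothing aborts the sweep.  Alongside each series the result
    carries its decreasing-pair count and consistent/inconsistent call
    (``'not_applicable'`` when the series has fewer than two numeric values).
    """
    if clusterer is None:
        if family not in SWEEP_CLUSTERERS:
            raise DbcvError(f"no default sweep clusterer for family {family!r}")
        clusterer = SWEEP_CLUSTERERS[family]
    for m in metric_names:
        if m not in _METRICS:
            raise DbcvError(f"metric {m!r} is not registered")
    values: dict[str, list] = {m: [] for m in metric_names}
    n_clusters = []
    levels = tuple(range(N_LEVELS))
    for level in levels:
        ds = generate(family, level, seed, **generate_kwargs)
        labels = backends.run_clusterer(ds.points, clusterer)
        n_clusters.append(int(np.unique(labels[labels != NOISE_LABEL]).size))
        for m in metric_names:
            values[m].append(evaluate_metric(m, ds.points, labels))
    series = {m: MetricSeries(m, tuple(values[m])) for m in metric_names}
    dec, cls = {}, {}
    for m in metric_names:
        try:
            dec[m] = decreasing_pair_count(series[m].values)
            cls[m] = classify_noise_trend(series[m].values)
        except UndefinedTrendError:
            dec[m] = NOT_APPLICABLE
            cls[m] = "not_applicable"
    return SweepResult(
        family=family,
        seed=int(seed),
        clusterer=clusterer,
        levels=levels,
        n_clusters=tuple(n_clusters),
        series=series,
        decreasing_pairs=dec,
        classification=cls,
    )


def run_trend_protocol(
    points,
    metric_names: Sequence[str] = ("dbcv",),
    seed: int = 0,
    configs_random: dict[str, backends.ClustererConfig] | None = None,
    configs_default: dict[str, backends.ClustererConfig] | None = None,
) -> list[TrendRecord]:
    """ARI-trend consistency of each metric over the three density clusterers.

    ``points`` is a preprocessed numeric matrix.  Each clusterer is run under
    a "random" configuration (drawn with ``seed`` unless given explicitly)
    and its default configuration; the two average pairwise ARIs anchor the
    expected direction of change, and each (metric, clusterer) pair gets a
    verdict from :func:`trend_verdict`.
    """
    X = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    if configs_random is None:
        configs_random = {
            m: backends.sample_random_params(m, seed=int(rng.integers(2**31)))
            for m in backends.METHODS
        }
    if configs_default is None:
        configs_default = {m: backends.default_params(m) for m in backends.METHODS}
    for m in metric_names:
        if m not in _METRICS:
            raise DbcvError(f"metric {m!r} is not registered")

    labels_random = {m: backends.run_clusterer(X, configs_random[m]) for m in backends.METHODS}
    labels_default = {m: backends.run_clusterer(X, configs_default[m]) for m in backends.METHODS}
    ari_random = average_pairwise_ari(*(labels_random[m] for m in backends.METHODS))
    ari_default = average_pairwise_ari(*(labels_default[m] for m in backends.METHODS))

    records = []
    for metric in metric_names:
        for method in backends.METHODS:
            vr = evaluate_metric(metric, X, labels_random[method])
            vd = evaluate_metric(metric, X, labels_default[method])
            records.append(
                TrendRecord(
                    metric_name=metric,
                    clusterer=method,
                    value_random=vr,
                    value_default=vd,
                    ari_random=ari_random,
                    ari_default=ari_default,
                    verdict=trend_verdict(vr, vd, ari_random, ari_default),
                )
            )
    return records


def tuned_degraded_configs(points) -> tuple[dict, dict]:
    """Data-driven tuned and degraded clusterer settings for one dataset.

    Tuned settings follow standard heuristics — DBSCAN eps at 1.5x the
    median 5th-nearest-neighbour distance, HDBSCAN's small default minimum
    cluster size, MeanShift's quantile bandwidth estimate — so that planted
    structure is recoverable.  Degraded settings halve the density scales
    (eps and bandwidth) and inflate the minimum cluster size to a quarter of
    the dataset, fragmenting or swallowing real clusters.  Used by the
    tuned-vs-degraded variant of the ARI-trend protocol.
    """
    from sklearn.cluster import estimate_bandwidth
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    d5 = float(
        np.median(NearestNeighbors(n_neighbors=6).fit(X).kneighbors(X)[0][:, 5])
    )
    bw = float(estimate_bandwidth(X, quantile=backends.MEANSHIFT_BANDWIDTH_QUANTILE))
    if bw <= 0:
        bw = max(d5, 1e-6)
    tuned = {
        "dbscan": backends.ClustererConfig("dbscan", {"eps": 1.5 * d5, "min_samples": 5}),
        "hdbscan": backends.ClustererConfig(
            "hdbscan", {"min_cluster_size": 5, "cluster_selection_epsilon": 0.0}
        ),
        "meanshift": backends.ClustererConfig("meanshift", {"bandwidth": bw}),
    }
    degraded = {
        "dbscan": backends.ClustererConfig(
            "dbscan", {"eps": 0.75 * d5, "min_samples": 5}
        ),
        "hdbscan": backends.ClustererConfig(
            "hdbscan",
            {"min_cluster_size": max(10, n // 4), "cluster_selection_epsilon": 0.0},
        ),
        "meanshift": backends.ClustererConfig("meanshift", {"bandwidth": 0.5 * bw}),
    }
    return tuned, degraded
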