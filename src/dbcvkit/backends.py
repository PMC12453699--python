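"""Uniform adapters over DBSCAN, HDBSCAN, and MeanShift.

The three density clusterers are run through scikit-learn; this module only
normalizes their configuration (default vs randomly drawn hyperparameters),
canonicalizes their output labels (noise sentinel -1, clusters renumbered
0..k-1 in order of first appearance), and provides the mixed-type
preprocessing needed before clustering an EHR-like table.

Default hyperparameters: DBSCAN eps=0.5, min_samples=5; HDBSCAN
min_cluster_size=5, cluster_selection_epsilon=0.0; MeanShift bandwidth
estimated at fit time with scikit-learn's quantile-based estimator
(quantile 0.3).  Random draws: MeanShift bandwidth ~ U(0.1, 5); the DBSCAN /
HDBSCAN ranges are configurable envelopes around the draws the protocols use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, HDBSCAN, MeanShift, estimate_bandwidth

from .dbcv import NOISE_LABEL
from .exceptions import DbcvError

METHODS = ("dbscan", "hdbscan", "meanshift")

MEANSHIFT_BANDWIDTH_QUANTILE = 0.3

#: Sampling envelopes for random hyperparameters; chosen to cover every draw
#: the trend protocol realizes, and overridable per call.
DEFAULT_RANDOM_RANGES = {
    "dbscan": {"eps": (0.1, 1.5), "min_samples": (3, 15)},
    "hdbscan": {"min_cluster_size": (5, 20), "cluster_selection_epsilon": (0.0, 1.0)},
    "meanshift": {"bandwidth": (0.1, 5.0)},
}

__all__ = [
    "METHODS",
    "ClustererConfig",
    "default_params",
    "sample_random_params",
    "run_clusterer",
    "preprocess_mixed",
    "canonicalize_labels",
]


@dataclass(frozen=True)
class ClustererConfig:
    """One clusterer plus its hyperparameters.

    ``params`` values are in the units of the (preprocessed) feature space.
    A ``bandwidth`` of ``None`` for MeanShift means estimate-at-fit.
    """

    method: str
    params: dict = field(default_factory=dict)
    mode: str = "default"
    seed: int | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise DbcvError(f"unknown method {self.method!r}; choose from {METHODS}")
        p = self.params
        if self.method == "dbscan":
            if p.get("eps", 0.5) <= 0 or p.get("min_samples", 5) < 1:
                raise DbcvError("DBSCAN needs eps > 0 and min_samples >= 1")
        elif self.method == "hdbscan":
            if p.get("min_cluster_size", 5) < 2 or p.get("cluster_selection_epsilon", 0.0) < 0:
                raise DbcvError("HDBSCAN needs min_cluster_size >= 2 and epsilon >= 0")
        elif self.method == "meanshift":
            bw = p.get("bandwidth")
            if bw is not None and bw <= 0:
                raise DbcvError("MeanShift bandwidth must be positive when given")


def default_params(method: str) -> ClustererConfig:
    """The published default configuration for ``method``."""
    if method == "dbscan":
        return ClustererConfig("dbscan", {"eps": 0.5, "min_samples": 5}, mode="default")
    if method == "hdbscan":
        return ClustererConfig(
            "hdbscan",
            {"min_cluster_size": 5, "cluster_selection_epsilon": 0.0},
            mode="default",
        )
    if method == "meanshift":
        # bandwidth=None -> quantile-based estimate at fit time
        return ClustererConfig("meanshift", {"bandwidth": None}, mode="default")
    raise DbcvError(f"unknown method {method!r}; choose from {METHODS}")


def sample_random_params(
    method: str, ranges: dict | None = None, seed: int | None = None
) -> ClustererConfig:
    """Draw a random configuration for ``method`` from the given envelopes.

    Real-valued parameters are uniform on their interval; integer parameters
    (``min_samples``, ``min_cluster_size``) are uniform on the inclusive
    integer range.  Reproducible under ``seed``.
    """
    if method not in METHODS:
        raise DbcvError(f"unknown method {method!r}; choose from {METHODS}")
    env = dict(DEFAULT_RANDOM_RANGES[method])
    if ranges:
        env.update(ranges)
    rng = np.random.default_rng(seed)
    params: dict = {}
    for name, (lo, hi) in env.items():
        if lo > hi:
            raise DbcvError(f"empty range for {name}: ({lo}, {hi})")
        if name in ("min_samples", "min_cluster_size"):
            params[name] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return ClustererConfig(method, params, mode="random", seed=seed)


def canonicalize_labels(labels, noise_label: int = NOISE_LABEL) -> np.ndarray:
    """Renumber cluster ids to 0..k-1 in order of first appearance; noise -> -1."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, noise_label, dtype=int)
    nxt = 0
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab == noise_label:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def run_clusterer(points, config: ClustererConfig) -> np.ndarray:
    """Cluster ``points`` with the configured backend.

    Returns one canonical label per point; unclustered points carry the
    noise sentinel -1.  Deterministic for fixed inputs and config (the
    backends used are deterministic given their hyperparameters).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise DbcvError("points must be a finite 2-D array")
    p = config.params
    if config.method == "dbscan":
        model = DBSCAN(eps=p.get("eps", 0.5), min_samples=p.get("min_samples", 5))
        labels = model.fit_predict(X)
    elif config.method == "hdbscan":
        model = HDBSCAN(
            min_cluster_size=p.get("min_cluster_size", 5),
            cluster_selection_epsilon=p.get("cluster_selection_epsilon", 0.0),
            copy=True,
        )
        labels = model.fit_predict(X)
    else:  # meanshift
        bw = p.get("bandwidth")
        if bw is None:
            bw = estimate_bandwidth(X, quantile=MEANSHIFT_BANDWIDTH_QUANTILE)
            if bw <= 0:
                # degenerate estimate (e.g. many duplicate rows): every point
                # is its own mode; report one cluster instead of failing
                return np.zeros(X.shape[0], dtype=int)
        model = MeanShift(bandwidth=float(bw))
        labels = model.fit_predict(X)
    return canonicalize_labels(labels)


def preprocess_mixed(table: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Encode a type-tagged mixed table as a numeric matrix for clustering.

    Column types are read from the name prefix: ``num_`` (standardized,
    median-imputed), ``ord_`` (integer ranks, standardized, median-imputed),
    ``bin_`` (mapped to {0, 1}, mode-imputed), ``cat_`` (one-hot encoded,
    mode-imputed).  Zero-variance columns are dropped with a warning.

    Returns ``(matrix, record)`` where ``record`` documents the applied
    transformation per column (for provenance).
    """
    if not isinstance(table, pd.DataFrame) or table.shape[0] < 1:
        raise DbcvError("preprocess_mixed needs a non-empty DataFrame")
    blocks: list[np.ndarray] = []
    record: dict = {"columns": {}, "dropped": []}
    for col in table.columns:
        kind = str(col).split("_", 1)[0]
        if kind not in ("num", "ord", "bin", "cat"):
            raise DbcvError(f"column {col!r} lacks a type tag (num/ord/cat/bin prefix)")
        s = table[col]
        if s.dropna().nunique() <= 1:
            record["dropped"].append(str(col))
            warnings.warn(f"dropping zero-variance column {col!r}", stacklevel=2)
            continue
        if kind in ("num", "ord"):
            v = pd.to_numeric(s, errors="coerce").astype(float)
            if kind == "ord":
                # map observed levels to consecutive integer ranks
                levels = np.sort(v.dropna().unique())
                v = v.map({lv: r for r, lv in enumerate(levels)}).astype(float)
            med = float(v.median())
            v = v.fillna(med).to_numpy()
            mu, sd = v.mean(), v.std()
            blocks.append(((v - mu) / sd)[:, None])
            record["columns"][str(col)] = {
                "kind": kind, "impute": med, "mean": float(mu), "std": float(sd),
            }
        elif kind == "bin":
            mode = s.mode(dropna=True).iloc[0]
            v = s.fillna(mode)
            levels = np.sort(v.unique())
            if levels.size > 2:
                raise DbcvError(f"binary column {col!r} has {levels.size} levels")
            v = (v == levels[-1]).astype(float).to_numpy()
            blocks.append(v[:, None])
            record["columns"][str(col)] = {"kind": kind, "impute": mode, "one": levels[-1]}
        else:  # cat
            mode = s.mode(dropna=True).iloc[0]
            v = s.fillna(mode)
            dummies = pd.get_dummies(v, prefix=str(col)).astype(float)
            blocks.append(dummies.to_numpy())
            record["columns"][str(col)] = {
                "kind": kind, "impute": mode, "levels": [str(c) for c in dummies.columns],
            }
    if not blocks:
        raise DbcvError("no usable columns after preprocessing")
    return np.hstack(blocks), record
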