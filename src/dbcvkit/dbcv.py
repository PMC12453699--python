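"""Density-based cluster validity (DBCV).

The index scores a hard partition of points in ``R^d`` by density rather than
by centroid geometry, which makes it informative for concave, nested, or
noise-contaminated clusters where convex-shape indices (Silhouette,
Calinski-Harabasz, ...) mislead.  The construction:

1. **All-points-core-distance** (APCD): for a point ``x`` in cluster ``Ci``,
   the inverse-power generalized mean of its distances to every other member,

   ``APCD(x) = ( (1/(|Ci|-1)) * sum_j (1/KNN(x, j))**d )**(-1/d)``

   where ``KNN(x, j)`` is the distance from ``x`` to its *j*-th nearest
   cluster-mate and ``d`` the embedding dimension.  Small APCD = dense
   neighbourhood.
2. **Mutual reachability distance** (MRD): ``max(APCD(xi), APCD(xj), d(xi, xj))``
   with Euclidean ``d``; the edge weight of the density graph.
3. **Density sparseness** of a cluster (DSC): the maximum edge weight of the
   minimum spanning tree of the cluster's complete MRD graph.
4. **Density separation** of a cluster pair (DSPC): the minimum MRD over all
   cross-cluster point pairs.
5. **Cluster validity** ``VC(Ci) = (min_j DSPC(Ci, Cj) - DSC(Ci)) / max(...)``
   in ``[-1, 1]``, and the overall index is the cluster-size-weighted sum
   ``DBCV(C) = sum_i |Ci|/|X| * VC(Ci)`` where ``|X|`` counts *all* points,
   noise included, so heavy noise shrinks the score's magnitude.

Values near +1 indicate cohesive, well-separated density clusters; values
near -1 indicate misassignment; noise-labelled points (sentinel ``-1``)
join no cluster but still count in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .exceptions import (
    DbcvError,
    DegenerateClusterError,
    InsufficientClustersError,
    UndefinedValidityError,
)

NOISE_LABEL = -1

# VC denominator guard: below this, both sparseness and separation are treated
# as exactly zero and the validity is undefined.
_VC_EPS = 1e-12

__all__ = [
    "NOISE_LABEL",
    "ClusterBreakdown",
    "DbcvBreakdown",
    "apcd_values",
    "mutual_reachability",
    "reachability_graph",
    "density_sparseness",
    "density_separation",
    "cluster_validity",
    "dbcv_index",
    "dbcv_score",
]


@dataclass(frozen=True)
class ClusterBreakdown:
    """Per-cluster intermediate quantities of the DBCV computation."""

    label: int
    size: int
    dsc: float
    min_dspc: float
    vc: float
    weight: float


@dataclass(frozen=True)
class DbcvBreakdown:
    """Full decomposition of a DBCV evaluation.

    ``overall == sum(c.weight * c.vc for c in clusters)`` exactly, and the
    weights sum to ``(n - n_noise) / n``.
    """

    overall: float
    clusters: tuple[ClusterBreakdown, ...]
    n_points: int
    n_noise: int
    dspc_pairs: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall,
            "n_points": self.n_points,
            "n_noise": self.n_noise,
            "clusters": [
                {
                    "label": c.label,
                    "size": c.size,
                    "dsc": c.dsc,
                    "min_dspc": c.min_dspc,
                    "vc": c.vc,
                    "weight": c.weight,
                }
                for c in self.clusters
            ],
        }


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
        raise DbcvError(f"points must be a non-empty n x d array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise DbcvError("points must be finite")
    return pts


def apcd_values(cluster_points, d: int | None = None) -> np.ndarray:
    """All-points-core-distance of every member of one cluster.

    Parameters
    ----------
    cluster_points : array-like of shape (m, d)
        Coordinates of the cluster's members (m >= 2).
    d : int, optional
        Embedding dimension used as the generalized-mean exponent; defaults
        to the number of coordinate columns.

    Returns
    -------
    ndarray of shape (m,)
        APCD per member.  A member coincident with another (zero distance)
        gets the limiting value 0.
    """
    pts = _as_points(cluster_points)
    m = pts.shape[0]
    if m < 2:
        raise DegenerateClusterError(
            f"APCD needs a cluster of >= 2 members, got {m}"
        )
    if d is None:
        d = pts.shape[1]
    if d < 1:
        raise DbcvError(f"embedding dimension must be >= 1, got {d}")
    dist = cdist(pts, pts)
    # distances to the other m-1 members; (1/0)**d -> inf makes the mean inf
    # and the outer (-1/d) power collapse to the limiting APCD of 0.
    off = dist[~np.eye(m, dtype=bool)].reshape(m, m - 1)
    with np.errstate(divide="ignore"):
        inv_pow = off ** (-float(d))
    mean = inv_pow.mean(axis=1)
    with np.errstate(divide="ignore"):
        apcd = mean ** (-1.0 / d)
    apcd[np.isinf(mean)] = 0.0
    return apcd


def mutual_reachability(apcd_i, apcd_j, euclid_ij):
    """Mutual reachability distance ``max(APCD_i, APCD_j, d_ij)`` (vectorized)."""
    a, b, e = (np.asarray(x, dtype=float) for x in (apcd_i, apcd_j, euclid_ij))
    if np.any(a < 0) or np.any(b < 0) or np.any(e < 0):
        raise DbcvError("core and Euclidean distances must be nonnegative")
    out = np.maximum(np.maximum(a, b), e)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReachabilityGraph:
    """Pairwise Euclidean and mutual-reachability distances over clustered points.

    ``indices[i]`` maps row ``i`` of the matrices back to the original point
    index; ``apcd`` holds each clustered point's core distance (computed
    within its own cluster).
    """

    euclid: np.ndarray
    mrd: np.ndarray
    apcd: np.ndarray
    indices: np.ndarray

    def rows_of(self, member_indices) -> np.ndarray:
        """Rows of the matrices corresponding to original point indices."""
        lookup = {int(idx): row for row, idx in enumerate(self.indices)}
        try:
            return np.array([lookup[int(i)] for i in member_indices], dtype=int)
        except KeyError as exc:  # pragma: no cover - contract violation
            raise DbcvError(f"point {exc} is not part of the reachability graph") from exc


def reachability_graph(points, clusters: list[np.ndarray], d: int | None = None) -> ReachabilityGraph:
    """Build the MRD graph over all clustered points.

    ``clusters`` is a list of arrays of original point indices, one per
    cluster; points absent from every cluster (noise) are excluded from the
    graph.  Each point's APCD is computed within its own cluster only.
    """
    pts = _as_points(points)
    if d is None:
        d = pts.shape[1]
    order = np.concatenate(clusters).astype(int)
    apcd = np.empty(order.size, dtype=float)
    pos = 0
    for members in clusters:
        members = np.asarray(members, dtype=int)
        apcd[pos : pos + members.size] = apcd_values(pts[members], d=d)
        pos += members.size
    sub = pts[order]
    euclid = cdist(sub, sub)
    mrd = np.maximum(np.maximum(apcd[:, None], apcd[None, :]), euclid)
    np.fill_diagonal(mrd, 0.0)
    return ReachabilityGraph(euclid=euclid, mrd=mrd, apcd=apcd, indices=order)


def _mst_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges (i, j, w) of a deterministic MST of a dense symmetric graph.

    scipy's implementation scans edges in fixed (row, column) order, which
    realizes the mandated index-pair tie-breaking rule; DSC only depends on
    edge weights, for which any MST agrees.
    """
    tree = minimum_spanning_tree(weights).tocoo()
    return tree.row, tree.col, tree.data


def density_sparseness(member_indices, graph: ReachabilityGraph, mode: str = "all") -> float:
    """Density sparseness of a cluster: the largest MRD edge in its MST.

    ``mode='all'`` (default) takes the maximum over every MST edge — the
    literal reading of the printed definition.  ``mode='internal'`` restricts
    to edges whose two endpoints both have MST degree >= 2 (the original 2014
    convention) and falls back to all edges when no such edge exists (e.g.
    2- and 3-point clusters, where every MST edge touches a leaf).
    """
    rows = graph.rows_of(member_indices)
    if rows.size < 2:
        raise DegenerateClusterError("DSC needs a cluster of >= 2 members")
    if mode not in ("all", "internal"):
        raise DbcvError(f"unknown DSC mode {mode!r}")
    sub = graph.mrd[np.ix_(rows, rows)]
    if not np.all(np.isfinite(sub)):
        raise DbcvError("MRD submatrix must be finite")
    i, j, w = _mst_edges(sub)
    if mode == "internal" and rows.size > 2:
        deg = np.bincount(np.concatenate([i, j]), minlength=rows.size)
        keep = (deg[i] >= 2) & (deg[j] >= 2)
        if keep.any():
            w = w[keep]
    return float(w.max())


def _internal_node_mask(rows: np.ndarray, graph: ReachabilityGraph) -> np.ndarray:
    """Mask of cluster members with MST degree >= 2 (all-True fallback)."""
    sub = graph.mrd[np.ix_(rows, rows)]
    i, j, _ = _mst_edges(sub)
    deg = np.bincount(np.concatenate([i, j]), minlength=rows.size)
    mask = deg >= 2
    return mask if mask.any() else np.ones(rows.size, dtype=bool)


def density_separation(
    ci_indices, cj_indices, graph: ReachabilityGraph, mode: str = "all"
) -> float:
    """Density separation of two clusters: the minimum cross-pair MRD.

    ``mode='all'`` (default) minimizes over every cross pair, the literal
    printed definition.  ``mode='internal'`` restricts each side to its MST
    internal nodes (degree >= 2), the original 2014 convention, falling back
    to all members for clusters with no internal node (size <= 3 chains).
    """
    ri = graph.rows_of(ci_indices)
    rj = graph.rows_of(cj_indices)
    if ri.size == 0 or rj.size == 0:
        raise DbcvError("DSPC needs two non-empty clusters")
    if np.intersect1d(ri, rj).size:
        raise DbcvError("DSPC is defined for two distinct clusters")
    if mode == "internal":
        ri = ri[_internal_node_mask(ri, graph)]
        rj = rj[_internal_node_mask(rj, graph)]
    elif mode != "all":
        raise DbcvError(f"unknown DSPC mode {mode!r}")
    return float(graph.mrd[np.ix_(ri, rj)].min())


def cluster_validity(dsc: float, min_dspc: float) -> float:
    """Validity of one cluster: ``(DSPC - DSC) / max(DSPC, DSC)`` in [-1, 1]."""
    if dsc < 0 or min_dspc < 0:
        raise DbcvError("DSC and DSPC must be nonnegative")
    denom = max(dsc, min_dspc)
    if denom < _VC_EPS:
        raise UndefinedValidityError(
            "both sparseness and separation are zero; validity undefined"
        )
    return (min_dspc - dsc) / denom


def _extract_clusters(labels, noise_label: int, singletons: str):
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise DbcvError("labels must be one-dimensional")
    work = labels.copy()
    uniq = [u for u in np.unique(work) if u != noise_label]
    for u in uniq:
        members = np.flatnonzero(work == u)
        if members.size == 1:
            if singletons == "error":
                raise DegenerateClusterError(
                    f"cluster {u} has a single member; APCD is undefined "
                    "(pass singletons='noise' to demote it)"
                )
            elif singletons == "noise":
                work[members] = noise_label
            else:
                raise DbcvError(f"unknown singleton policy {singletons!r}")
    clusters = [
        (int(u), np.flatnonzero(work == u))
        for u in np.unique(work)
        if u != noise_label
    ]
    return work, clusters


def dbcv_index(
    points,
    labels,
    *,
    noise_label: int = NOISE_LABEL,
    singletons: str = "error",
    dsc_mode: str = "all",
    dspc_mode: str = "all",
    d: int | None = None,
) -> DbcvBreakdown:
    """Compute DBCV and its full per-cluster breakdown.

    Parameters
    ----------
    points : array-like of shape (n, d)
    labels : array-like of shape (n,)
        Integer cluster labels; ``noise_label`` marks unclustered points.
    singletons : {'error', 'noise'}
        Hard error on single-member clusters (default), or demote them to
        noise before scoring.
    dsc_mode, dspc_mode : {'all', 'internal'}
        Literal printed definitions (default) or the original internal-edge /
        internal-node convention used by the reference implementations; see
        :func:`density_sparseness` and :func:`density_separation`.
    d : int, optional
        Generalized-mean exponent; defaults to the coordinate dimension.

    Raises
    ------
    InsufficientClustersError
        Fewer than two clusters remain after noise handling.
    DegenerateClusterError
        A singleton cluster under the default policy.
    """
    pts = _as_points(points)
    labels = np.asarray(labels)
    if labels.shape[0] != pts.shape[0]:
        raise DbcvError(
            f"labels length {labels.shape[0]} != number of points {pts.shape[0]}"
        )
    work, clusters = _extract_clusters(labels, noise_label, singletons)
    if len(clusters) < 2:
        raise InsufficientClustersError(
            f"DBCV needs >= 2 clusters, got {len(clusters)}"
        )
    n = pts.shape[0]
    n_noise = int(np.sum(work == noise_label))
    graph = reachability_graph(pts, [m for _, m in clusters], d=d)

    k = len(clusters)
    dsc = np.array(
        [density_sparseness(m, graph, mode=dsc_mode) for _, m in clusters]
    )
    dspc = np.full((k, k), np.inf)
    pairs = {}
    for a in range(k):
        for b in range(a + 1, k):
            val = density_separation(
                clusters[a][1], clusters[b][1], graph, mode=dspc_mode
            )
            dspc[a, b] = dspc[b, a] = val
            pairs[(clusters[a][0], clusters[b][0])] = val
    min_dspc = dspc.min(axis=1)

    breakdown = []
    overall = 0.0
    for idx, (label, members) in enumerate(clusters):
        vc = cluster_validity(dsc[idx], min_dspc[idx])
        weight = members.size / n
        overall += weight * vc
        breakdown.append(
            ClusterBreakdown(
                label=label,
                size=int(members.size),
                dsc=float(dsc[idx]),
                min_dspc=float(min_dspc[idx]),
                vc=float(vc),
                weight=float(weight),
            )
        )
    return DbcvBreakdown(
        overall=float(overall),
        clusters=tuple(breakdown),
        n_points=n,
        n_noise=n_noise,
        dspc_pairs=pairs,
    )


def dbcv_score(points, labels, **kwargs) -> float:
    """Overall DBCV index (convenience wrapper around :func:`dbcv_index`)."""
    return dbcv_index(points, labels, **kwargs).overall
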