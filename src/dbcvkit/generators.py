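"""Seeded generators for the benchmark shape families and a synthetic EHR table.

Four planar families, each with a 10-step degradation schedule, exercise a
validity index on concave and nested structure:

* **half_moons** — 1,000 points on two interlocking crescents, Gaussian
  jitter sigma in ``{0.0, 0.056, ..., 0.5}``.
* **shifting_circles** — 500 points on an outer ring (radius 1.5) and 500 on
  an inner ring (radius 0.5) whose centre shifts by ``(0.2 * level, 0)``; the
  rings go from nested-and-separated to overlapping.  No jitter by default.
* **sparse_circles** — 1,000 points on two concentric rings (radius ratio
  0.5) with jitter ``sigma = 0.05 + 0.0555 * level``.
* **tulip** — a packaged synthetic crescent base cloud normalized to
  ``[0, 1]^2``, augmented with 400 points resampled from the base plus jitter
  (same sigma schedule as half moons) wrapped back into ``[0, 1]`` by modulo.

Every generator takes an explicit integer ``seed`` and is bit-for-bit
reproducible for the same ``(family, level_index, seed)``.  Ground-truth
memberships always accompany the coordinates.

:func:`gen_synthetic_ehr` emulates a mixed-type patient table (numeric,
ordinal, categorical, binary columns) with ``k`` planted groups, a tunable
effect size, and missingness — a stand-in for clustered clinical-record data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.datasets import make_circles, make_moons

from .exceptions import DbcvError

FAMILIES = ("half_moons", "shifting_circles", "sparse_circles", "tulip")
N_LEVELS = 10

# Jitter schedule shared by half_moons and tulip: 0.0 .. 0.5 in steps of ~0.056.
JITTER_SCHEDULE = (0.0, 0.056, 0.111, 0.167, 0.222, 0.278, 0.333, 0.389, 0.444, 0.5)
# Sparse circles: base sigma and per-level increment.
SPARSE_BASE_SIGMA = 0.05
SPARSE_SIGMA_STEP = 0.0555
# Shifting circles geometry.
INNER_RADIUS = 0.5
OUTER_RADIUS = 1.5
SHIFT_STEP = 0.2

_FAMILY_CODE = {name: i for i, name in enumerate(FAMILIES)}
_FAMILY_CODE["ehr_table"] = len(FAMILIES)

__all__ = [
    "FAMILIES",
    "N_LEVELS",
    "JITTER_SCHEDULE",
    "SPARSE_BASE_SIGMA",
    "SPARSE_SIGMA_STEP",
    "ShapeDataset",
    "EhrTableSpec",
    "gen_half_moons",
    "gen_shifting_circles",
    "gen_sparse_circles",
    "gen_tulip",
    "gen_synthetic_ehr",
    "generate",
    "tulip_base",
]


@dataclass(frozen=True)
class ShapeDataset:
    """A generated point cloud with provenance and ground-truth memberships."""

    points: np.ndarray
    truth: np.ndarray
    family: str
    level_index: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def _check_level(level_index: int) -> int:
    level_index = int(level_index)
    if not 0 <= level_index < N_LEVELS:
        raise DbcvError(f"level_index must be in [0, {N_LEVELS - 1}], got {level_index}")
    return level_index


def _rng(family: str, level_index: int, seed: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), _FAMILY_CODE[family], int(level_index)])
    return np.random.default_rng(ss)


def _sk_state(family: str, level_index: int, seed: int) -> int:
    # scikit-learn wants a plain int random_state; derive one stably.
    ss = np.random.SeedSequence([int(seed), _FAMILY_CODE[family], int(level_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def gen_half_moons(level_index: int, seed: int = 0) -> ShapeDataset:
    """Two interlocking crescents (1,000 points) at jitter level ``level_index``."""
    level_index = _check_level(level_index)
    sigma = JITTER_SCHEDULE[level_index]
    pts, truth = make_moons(
        n_samples=1000,
        noise=sigma if sigma > 0 else None,
        random_state=_sk_state("half_moons", level_index, seed),
    )
    return ShapeDataset(
        points=pts,
        truth=truth.astype(int),
        family="half_moons",
        level_index=level_index,
        seed=int(seed),
        meta={"sigma": sigma},
    )


def gen_shifting_circles(
    level_index: int, seed: int = 0, jitter: float = 0.0
) -> ShapeDataset:
    """Outer ring (r=1.5, 500 pts) and inner ring (r=0.5, 500 pts) shifted by
    ``(0.2 * level_index, 0)``.

    ``jitter`` adds optional Gaussian radial noise (default 0: exact circles).
    """
    level_index = _check_level(level_index)
    rng = _rng("shifting_circles", level_index, seed)
    shift = SHIFT_STEP * level_index
    theta_out = rng.uniform(0, 2 * np.pi, 500)
    theta_in = rng.uniform(0, 2 * np.pi, 500)
    r_out = OUTER_RADIUS + (rng.normal(0, jitter, 500) if jitter > 0 else 0.0)
    r_in = INNER_RADIUS + (rng.normal(0, jitter, 500) if jitter > 0 else 0.0)
    outer = np.column_stack([r_out * np.cos(theta_out), r_out * np.sin(theta_out)])
    inner = np.column_stack(
        [shift + r_in * np.cos(theta_in), r_in * np.sin(theta_in)]
    )
    pts = np.vstack([outer, inner])
    truth = np.repeat([0, 1], 500)
    return ShapeDataset(
        points=pts,
        truth=truth,
        family="shifting_circles",
        level_index=level_index,
        seed=int(seed),
        meta={"shift": shift, "jitter": jitter},
    )


def gen_sparse_circles(
    level_index: int, seed: int = 0, factor: float = 0.5
) -> ShapeDataset:
    """Two concentric rings (1,000 points) at jitter ``0.05 + 0.0555 * level``.

    ``factor`` is the inner/outer radius ratio (the study never states it;
    0.5 matches visibly separated rings).
    """
    level_index = _check_level(level_index)
    sigma = SPARSE_BASE_SIGMA + SPARSE_SIGMA_STEP * level_index
    pts, truth = make_circles(
        n_samples=1000,
        noise=sigma,
        factor=factor,
        random_state=_sk_state("sparse_circles", level_index, seed),
    )
    return ShapeDataset(
        points=pts,
        truth=truth.astype(int),
        family="sparse_circles",
        level_index=level_index,
        seed=int(seed),
        meta={"sigma": sigma, "factor": factor},
    )


def tulip_base() -> tuple[np.ndarray, np.ndarray]:
    """The packaged synthetic crescent base cloud, normalized to [0, 1]^2.

    A deterministic stand-in constructed from two parametric arcs; returns
    ``(points, truth)``.
    """
    ref = importlib.resources.files("dbcvkit.data") / "tulip_base_synthetic.csv"
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return df[["x", "y"]].to_numpy(dtype=float), df["truth"].to_numpy(dtype=int)


def _wrap_unit(values: np.ndarray) -> np.ndarray:
    # modulo wrap into [0, 1], but keep exact 1.0 (mod would send it to 0.0,
    # breaking the zero-jitter identity with the base points).
    out = np.mod(values, 1.0)
    out[values == 1.0] = 1.0
    return out


def gen_tulip(level_index: int, seed: int = 0, n_augment: int = 400) -> ShapeDataset:
    """Base crescent cloud plus ``n_augment`` jittered resampled points.

    The augmented points are sampled (with replacement) from the base,
    perturbed with Gaussian jitter at the level's sigma, and wrapped back
    into ``[0, 1]`` with the modulo operation; output = base followed by the
    augmented points.
    """
    level_index = _check_level(level_index)
    sigma = JITTER_SCHEDULE[level_index]
    base, base_truth = tulip_base()
    rng = _rng("tulip", level_index, seed)
    pick = rng.integers(0, base.shape[0], size=n_augment)
    extra = base[pick] + rng.normal(0.0, sigma, size=(n_augment, 2)) if sigma > 0 else base[pick].copy()
    extra = _wrap_unit(extra)
    pts = np.vstack([base, extra])
    truth = np.concatenate([base_truth, base_truth[pick]])
    return ShapeDataset(
        points=pts,
        truth=truth,
        family="tulip",
        level_index=level_index,
        seed=int(seed),
        meta={"sigma": sigma, "n_base": base.shape[0], "n_augment": n_augment},
    )


def generate(family: str, level_index: int, seed: int = 0, **kwargs) -> ShapeDataset:
    """Dispatch to the named family's generator."""
    table = {
        "half_moons": gen_half_moons,
        "shifting_circles": gen_shifting_circles,
        "sparse_circles": gen_sparse_circles,
        "tulip": gen_tulip,
    }
    if family not in table:
        raise DbcvError(f"unknown family {family!r}; choose from {FAMILIES}")
    return table[family](level_index, seed, **kwargs)


@dataclass(frozen=True)
class EhrTableSpec:
    """Shape and signal of a synthetic mixed-type patient table.

    Defaults emulate a small oncology registry: 168 rows, 13 features
    (7 numeric, 2 ordinal, 2 categorical, 2 binary), three latent patient
    groups separated by 4 within-group standard deviations, no missingness.
    """

    n_rows: int = 168
    n_numeric: int = 7
    n_ordinal: int = 2
    n_categorical: int = 2
    n_binary: int = 2
    k_groups: int = 3
    separation: float = 4.0
    missing_rate: float = 0.0
    n_categories: int = 3
    ordinal_levels: int = 4

    @property
    def n_features(self) -> int:
        return self.n_numeric + self.n_ordinal + self.n_categorical + self.n_binary

    def validate(self) -> "EhrTableSpec":
        if self.n_rows < 1 or self.k_groups < 1:
            raise DbcvError("n_rows and k_groups must be >= 1")
        if self.k_groups > self.n_rows:
            raise DbcvError("k_groups cannot exceed n_rows")
        if not 0 <= self.missing_rate < 1:
            raise DbcvError("missing_rate must be in [0, 1)")
        if min(self.n_numeric, self.n_ordinal, self.n_categorical, self.n_binary) < 0:
            raise DbcvError("feature counts must be nonnegative")
        return self


def _group_centers(rng, k: int, d: int, separation: float) -> np.ndarray:
    """k centres in R^d whose minimum pairwise distance equals ``separation``."""
    if d == 0 or k == 1 or separation == 0:
        return np.zeros((k, d))
    raw = rng.standard_normal((k, d))
    dists = np.sqrt(((raw[:, None, :] - raw[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dists, np.inf)
    dmin = dists.min()
    if dmin < 1e-9:  # pragma: no cover - essentially impossible draw
        raw += np.arange(k)[:, None]
        dists = np.sqrt(((raw[:, None, :] - raw[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        dmin = dists.min()
    return raw * (separation / dmin)


def gen_synthetic_ehr(
    spec: EhrTableSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mixed-type patient table with planted group structure.

    Numeric columns are unit-variance Gaussians around group centres whose
    minimum pairwise distance is ``spec.separation``; ordinal columns are
    group-shifted latent normals cut into equal-frequency levels; categorical
    and binary columns have softmax group-dependent category probabilities
    (uniform when ``separation == 0``).  Missing cells (NaN) are planted
    uniformly at ``missing_rate``.  Column names are tagged by type:
    ``num_*``, ``ord_*``, ``cat_*``, ``bin_*``.

    Returns ``(table, planted_labels)``.
    """
    spec = (spec or EhrTableSpec()).validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _FAMILY_CODE["ehr_table"]]))
    n, k = spec.n_rows, spec.k_groups
    # balanced group sizes (remainder spread over the first groups)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    rng.shuffle(labels)

    cols: dict[str, np.ndarray] = {}
    centers = _group_centers(rng, k, spec.n_numeric, spec.separation)
    for j in range(spec.n_numeric):
        cols[f"num_{j}"] = centers[labels, j] + rng.standard_normal(n)

    # ordinal: latent group-shifted normal, cut at pooled equal-frequency bins
    ord_shift = _group_centers(rng, k, spec.n_ordinal, spec.separation / 2.0)
    for j in range(spec.n_ordinal):
        latent = ord_shift[labels, j] + rng.standard_normal(n)
        qs = np.quantile(latent, np.linspace(0, 1, spec.ordinal_levels + 1)[1:-1])
        cols[f"ord_{j}"] = np.digitize(latent, qs).astype(float)

    for j in range(spec.n_categorical):
        logits = np.zeros((k, spec.n_categories))
        for g in range(k):
            logits[g, g % spec.n_categories] = spec.separation / 2.0
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        draws = np.array([rng.choice(spec.n_categories, p=probs[g]) for g in labels])
        cols[f"cat_{j}"] = draws.astype(float)

    for j in range(spec.n_binary):
        sign = np.where((np.arange(k) + j) % 2 == 0, 1.0, -1.0)
        p = 1.0 / (1.0 + np.exp(-spec.separation / 2.0 * sign))
        cols[f"bin_{j}"] = (rng.random(n) < p[labels]).astype(float)

    df = pd.DataFrame(cols)
    if spec.missing_rate > 0:
        mask = rng.random(df.shape) < spec.missing_rate
        df = df.mask(mask)
    return df, labels
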