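"""Delimited-text readers/writers, report serialization, and run manifests.

Conventions: comma-separated files with a header; coordinate columns are
numeric; a ``label`` column holds clustering labels with -1 reserved for
noise; a ``truth`` column holds ground-truth memberships.  Missing/N-A cells
are written as the explicit token ``NA``; floats are serialized with 12
significant digits.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DbcvError
from .generators import ShapeDataset

NA_TOKEN = "NA"
FLOAT_FMT = "%.12g"

__all__ = [
    "read_points",
    "write_points",
    "write_report",
    "RunManifest",
    "write_manifest",
    "file_digest",
]


def read_points(path) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Read a delimited point file.

    Returns ``(points, labels, truth)``; ``labels``/``truth`` are None when
    the corresponding column is absent.  Raises on empty files, ragged rows,
    or non-numeric coordinate cells (with the offending location).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DbcvError(f"{path}: empty input file") from exc
    except pd.errors.ParserError as exc:
        raise DbcvError(f"{path}: malformed delimited text ({exc})") from exc
    if df.shape[0] == 0:
        raise DbcvError(f"{path}: no data rows")
    labels = truth = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    if "truth" in df.columns:
        truth = df.pop("truth").to_numpy(dtype=int)
    coords = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise DbcvError(
                f"{path}: non-numeric coordinate at row {row + 2}, column {col!r}"
            )
        coords[:, j] = converted.to_numpy()
    if coords.shape[1] == 0:
        raise DbcvError(f"{path}: no coordinate columns")
    return coords, labels, truth


def write_points(dataset, path, labels=None) -> Path:
    """Write points (a ShapeDataset or an (n, d) array) as CSV.

    ShapeDatasets carry their truth column; an optional ``labels`` array adds
    a ``label`` column.
    """
    path = Path(path)
    if isinstance(dataset, ShapeDataset):
        pts, truth = dataset.points, dataset.truth
    else:
        pts, truth = np.asarray(dataset, dtype=float), None
    cols = {f"x{j}": pts[:, j] for j in range(pts.shape[1])}
    df = pd.DataFrame(cols)
    if truth is not None:
        df["truth"] = truth
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def _jsonable(obj):
    if obj is None:
        return None
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        if not np.isfinite(obj):
            return None  # explicit N/A marker in JSON
        # 12 significant digits, round-trippable
        return float(f"{float(obj):.12g}")
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_report(result, path, format: str = "json") -> Path:
    """Serialize a result object (dataclass / dict / DataFrame) to disk.

    ``format='json'`` writes a JSON document; ``format='csv'`` expects a
    DataFrame (or a dict of equal-length columns) and writes delimited text
    with ``NA`` markers and stable column order.
    """
    path = Path(path)
    if format == "json":
        payload = _jsonable(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "csv":
        df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
        df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format=FLOAT_FMT)
    else:
        raise DbcvError(f"unknown report format {format!r}")
    return path


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record paired with every emitted result file."""

    command: str
    seeds: dict
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    package_version: str = ""
    created_unix: float = field(default_factory=time.time)

    @property
    def config_digest(self) -> str:
        canon = json.dumps(_jsonable(self.config), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    payload = _jsonable(asdict(manifest))
    payload["config_digest"] = manifest.config_digest
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
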