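"""Functional-connectivity matrices: computation, thresholding, standardisation, I/O.

Connectivity is the ROI-by-ROI Pearson correlation of mean BOLD time series.
Downstream factorization consumes the positive part only (non-negative input
constraint); graph construction keeps the strongest fraction of edges.
Self-edges (the diagonal) are never part of edge sets or threshold statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "NonnegConnectivity",
    "compute_fc",
    "threshold_positive",
    "threshold_top_fraction",
    "zscore_matrix",
    "fisher_z",
    "read_matrix",
    "write_matrix",
]

_SYM_TOL = 1e-10


@dataclass
class TimeSeriesMatrix:
    """T x N matrix of regional time series (time points by ROIs)."""

    values: np.ndarray
    subject_id: str = ""
    task_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("time series must be a T x N matrix with T >= 3")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite entries")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N correlation matrix for one subject and task."""

    values: np.ndarray
    subject_id: str = ""
    task_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise ValueError("connectivity matrix not symmetric within 1e-10")
        if v.min() < -1.0 - 1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class NonnegConnectivity(ConnectivityMatrix):
    """Positive part of a connectivity matrix: the factorization input X_k."""

    def __post_init__(self):
        super().__post_init__()
        if self.values.min() < 0:
            raise ValueError("non-negative connectivity has negative entries")


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all ROI pairs of a time-series matrix.

    Raises if any ROI's series has zero variance (correlation undefined),
    naming the offending 1-based ROI index.
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance time series for ROI(s) {[int(b) + 1 for b in bad]}"
        )
    c = np.corrcoef(x, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, subject_id=ts.subject_id, task_id=ts.task_id)


def threshold_positive(fc: ConnectivityMatrix) -> NonnegConnectivity:
    """Keep only positive correlations; entries <= 0 become 0.

    The result is the non-negative input matrix consumed by the joint
    factorization. Idempotent.
    """
    v = np.where(fc.values > 0, fc.values, 0.0)
    return NonnegConnectivity(values=v, subject_id=fc.subject_id, task_id=fc.task_id)


def threshold_top_fraction(
    fc: ConnectivityMatrix, fraction: float
) -> list[tuple[int, int]]:
    """Strongest `fraction` of off-diagonal upper-triangle entries, as (i, j) pairs.

    Keeps ceil(fraction * N(N-1)/2) edges ranked by value, ties broken by
    lexicographic (i, j) with lower indices first. Indices are 0-based.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = fc.n_rois
    iu, ju = np.triu_indices(n, k=1)
    vals = fc.values[iu, ju]
    k = math.ceil(fraction * len(vals))
    # sort by (-value, i, j): highest values first, lexicographic tie-break
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    return [(int(iu[e]), int(ju[e])) for e in keep]


def zscore_matrix(fc: ConnectivityMatrix) -> np.ndarray:
    """Off-diagonal entries standardised to mean 0, sd 1; diagonal untouched.

    Returns a plain array: the result is a standardized feature matrix, not
    a correlation matrix.
    """
    v = fc.values.copy()
    n = fc.n_rois
    off = ~np.eye(n, dtype=bool)
    mu = v[off].mean()
    sd = v[off].std()
    if sd == 0:
        raise ValueError("off-diagonal entries are constant; z-score undefined")
    v[off] = (v[off] - mu) / sd
    return v


def fisher_z(fc: ConnectivityMatrix, clip: float = 0.999999) -> np.ndarray:
    """Fisher r-to-z transform atanh(r) as a plain array (|r| clipped below 1)."""
    return np.arctanh(np.clip(fc.values, -clip, clip))


# ---------------------------------------------------------------------------
# I/O: dense delimited text + optional JSON sidecar carrying subject/task ids.

def write_matrix(fc: ConnectivityMatrix, path, sidecar: bool = True) -> None:
    path = Path(path)
    np.savetxt(path, fc.values, fmt="%.17g", delimiter="\t")
    if sidecar:
        meta = {"subject_id": fc.subject_id, "task_id": fc.task_id}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    first = path.read_text().splitlines()[0]
    delim = "," if ("," in first) else None  # None: any whitespace
    v = np.loadtxt(path, delimiter=delim)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {v.shape}")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(
        values=v,
        subject_id=meta.get("subject_id", ""),
        task_id=meta.get("task_id", ""),
    )
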