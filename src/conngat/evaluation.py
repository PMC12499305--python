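"""Splits, metrics, repeated experiments, bootstrap comparison and baselines.

The evaluation protocol mirrors the study design: an 80/10/10
train/validation/test split stratified over equal-width age bins, RMSE / MAE /
Pearson r on the test set, repeated over independent seeded splits and
reported as mean +/- sd, with paired t-tests and bootstrap resampling for
pairwise model comparison.  A 10-fold cross-validation protocol is available
as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .connectivity import ConnectivityMatrix, threshold_top_fraction, zscore_matrix
from .data import CohortData

__all__ = [
    "SplitPlan",
    "Metrics",
    "EvalReport",
    "stratified_split",
    "metrics",
    "repeated_experiments",
    "bootstrap_compare",
    "baselines",
]


@dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    ratios: tuple = (0.8, 0.1, 0.1)
    n_bins: int = 5
    seed: int = 0

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        parts = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(parts)) != len(parts):
            raise ValueError("split partitions overlap")


def _largest_remainder(n: int, ratios) -> list[int]:
    raw = [n * r for r in ratios]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    # hand the leftover units to the largest fractional parts (stable order)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(ages, ratios=(0.8, 0.1, 0.1), n_bins: int = 5,
                     seed: int = 0) -> SplitPlan:
    """Seeded stratified split over equal-width age bins.

    Within each bin indices are shuffled and allocated to the partitions by
    largest-remainder rounding, so every bin's train share is within one
    subject of the target ratio.
    """
    ages = np.asarray(ages, dtype=float)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = ages.min(), ages.max()
    if hi == lo:
        bins = np.zeros(len(ages), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(ages, edges[1:-1]), 0, n_bins - 1)
    parts: list[list[int]] = [[], [], []]
    for b in range(n_bins):
        idx = np.flatnonzero(bins == b)
        if idx.size == 0:
            continue
        if idx.size < len(ratios):
            warnings.warn(
                f"age bin {b} has {idx.size} subject(s), fewer than the "
                "number of partitions; falling back to remainder allocation"
            )
        idx = rng.permutation(idx)
        sizes = _largest_remainder(idx.size, ratios)
        cut1, cut2 = sizes[0], sizes[0] + sizes[1]
        parts[0].extend(idx[:cut1].tolist())
        parts[1].extend(idx[cut1:cut2].tolist())
        parts[2].extend(idx[cut2:].tolist())
    return SplitPlan(
        train=np.sort(parts[0]), val=np.sort(parts[1]), test=np.sort(parts[2]),
        ratios=tuple(ratios), n_bins=n_bins, seed=seed,
    )


@dataclass
class Metrics:
    rmse: float
    mae: float
    pearson_r: float  # NaN when undefined (constant inputs)

    def astuple(self):
        return (self.rmse, self.mae, self.pearson_r)


def metrics(y, y_hat) -> Metrics:
    """RMSE, MAE and Pearson r; r is NaN when either vector is constant."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size < 2 or y_hat.size != y.size:
        raise ValueError("need >= 2 paired observations")
    resid = y_hat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if (y == y[0]).all() or (y_hat == y_hat[0]).all():
        r = float("nan")
    else:
        r = float(stats.pearsonr(y, y_hat).statistic)
    return Metrics(rmse=rmse, mae=mae, pearson_r=r)


@dataclass
class EvalReport:
    per_repeat: list  # list of Metrics
    n_repeats: int
    comparisons: dict = field(default_factory=dict)

    def _col(self, name):
        return np.array([getattr(m, name) for m in self.per_repeat])

    def summary(self) -> dict:
        out = {}
        for name in ("rmse", "mae", "pearson_r"):
            col = self._col(name)
            if np.isnan(col).all():
                out[name] = {"mean": float("nan"), "std": float("nan")}
            else:
                out[name] = {"mean": float(np.nanmean(col)),
                             "std": float(np.nanstd(col))}
        out["n_repeats"] = self.n_repeats
        return out

    def __str__(self) -> str:
        s = self.summary()
        return (
            f"RMSE {s['rmse']['mean']:.4f} ± {s['rmse']['std']:.4f}  "
            f"MAE {s['mae']['mean']:.4f} ± {s['mae']['std']:.4f}  "
            f"r {s['pearson_r']['mean']:.4f} ± {s['pearson_r']['std']:.4f}  "
            f"({self.n_repeats} repeats)"
        )


def repeated_experiments(
    data: CohortData,
    fit_predict,
    n_repeats: int = 10,
    seeds=None,
    ratios=(0.8, 0.1, 0.1),
    n_bins: int = 5,
    protocol: str = "holdout",
) -> EvalReport:
    """Repeat (split, train, test) and aggregate metrics.

    `fit_predict(data, train_idx, test_idx, seed)` must return test-set
    predictions.  protocol "holdout" draws a fresh stratified split per
    repeat; "cv" runs seeded 10-fold cross-validation per repeat and pools
    the fold predictions.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    results = []
    for rep, seed in enumerate(seeds):
        try:
            if protocol == "holdout":
                plan = stratified_split(data.ages, ratios, n_bins, seed)
                preds = fit_predict(data, plan.train, plan.test, seed)
                results.append(metrics(data.ages[plan.test], preds))
            elif protocol == "cv":
                rng = np.random.default_rng(seed)
                order = rng.permutation(data.n_subjects)
                folds = np.array_split(order, 10)
                y_all, p_all = [], []
                for f in range(10):
                    test_idx = folds[f]
                    train_idx = np.concatenate([folds[g] for g in range(10) if g != f])
                    p_all.append(fit_predict(data, train_idx, test_idx, seed))
                    y_all.append(data.ages[test_idx])
                results.append(metrics(np.concatenate(y_all), np.concatenate(p_all)))
            else:
                raise ValueError(f"unknown protocol {protocol!r}")
        except Exception as exc:
            raise RuntimeError(f"repeat {rep} (seed {seed}) failed: {exc}") from exc
    return EvalReport(per_repeat=results, n_repeats=n_repeats)


def bootstrap_compare(metric_a, metric_b, n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired t-test plus a bootstrap p-value on per-repeat metric differences.

    The bootstrap resamples the paired differences with replacement to build
    the empirical distribution of the paired t statistic (bootstrap-t): the
    two-sided p is the add-one-smoothed share of resampled statistics
    t* = (mean* - mean_obs) / se* at least as extreme as the observed
    t = mean_obs / se_obs.  A zero-variance difference vector flags the
    t-test as degenerate and gives bootstrap p = 1 (no resample crosses).
    """
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    d = a - b
    n = d.size
    degenerate = bool(np.std(d, ddof=1) == 0)
    if degenerate:
        return {"t_p": float("nan"), "bootstrap_p": 1.0, "degenerate": True}
    t_p = float(stats.ttest_rel(a, b).pvalue)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = d[idx]
    obs = d.mean()
    se_star = samples.std(axis=1, ddof=1) / np.sqrt(n)
    m_star = samples.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(
            se_star > 0, (m_star - obs) / se_star,
            np.where(m_star == obs, 0.0, np.inf),
        )
    t_obs = obs / (d.std(ddof=1) / np.sqrt(n))
    extreme = int(np.sum(np.abs(t_star) >= abs(t_obs)))
    boot_p = min(1.0, (1 + extreme) / (1 + n_boot))
    return {"t_p": t_p, "bootstrap_p": boot_p, "degenerate": degenerate}


# ---------------------------------------------------------------------------
# Simple comparator arms

def _edge_features(data: CohortData, idx) -> np.ndarray:
    """Flattened z-scored upper-triangle connectivity, top-10% edges per task.

    The edge set is fixed from the group-mean connectivity so train and test
    subjects share a feature space.
    """
    n = data.n_rois
    feats = []
    for t in data.tasks:
        mean_fc = np.mean(
            [np.abs(data.fc[(s, t)].values) for s in data.subjects], axis=0
        )
        np.fill_diagonal(mean_fc, 1.0)
        edges = threshold_top_fraction(ConnectivityMatrix(values=mean_fc), 0.10)
        ii = np.array([e[0] for e in edges])
        jj = np.array([e[1] for e in edges])
        block = np.stack(
            [zscore_matrix(data.fc[(data.subjects[i], t)])[ii, jj] for i in idx]
        )
        feats.append(block)
    return np.concatenate(feats, axis=1)


def baselines(data: CohortData, which, train_idx, test_idx, seed: int = 0,
              gnn_kwargs: dict | None = None) -> dict:
    """Fit the named comparators on one split; returns {name: Metrics}.

    mean: constant mean-age predictor. linear / mlp: regressions on z-scored
    top-10% edge features. gat_plain: the attention model on raw connectivity
    rows (no factorization). gcn_plain: the same with uniform neighbor
    weights instead of attention.
    """
    from .model import ConnectomeGATRegressor

    known = {"mean", "linear", "mlp", "gcn_plain", "gat_plain"}
    unknown = set(which) - known
    if unknown:
        raise ValueError(f"unknown baseline name(s): {sorted(unknown)}")
    train_idx = np.asarray(train_idx, int)
    test_idx = np.asarray(test_idx, int)
    y_tr, y_te = data.ages[train_idx], data.ages[test_idx]
    out = {}
    if {"linear", "mlp"} & set(which):
        f_tr = _edge_features(data, train_idx)
        f_te = _edge_features(data, test_idx)
    for name in which:
        if name == "mean":
            pred = np.full(len(test_idx), y_tr.mean())
        elif name == "linear":
            pred = LinearRegression().fit(f_tr, y_tr).predict(f_te)
        elif name == "mlp":
            pred = MLPRegressor(
                hidden_layer_sizes=(100,), max_iter=2000, random_state=seed
            ).fit(f_tr, y_tr).predict(f_te)
        else:
            est = ConnectomeGATRegressor(
                feature_mode="fc",
                attention=(name == "gat_plain"),
                seed=seed,
                **(gnn_kwargs or {}),
            )
            est.fit(data, train_idx=train_idx)
            pred = est.predict(data, idx=test_idx)
        out[name] = metrics(y_te, pred)
    return out
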