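"""Joint non-negative matrix factorization with a basis shared across matrices.

Given K non-negative matrices X_1..X_K (one per subject-task connectivity
matrix), find a single non-negative basis W (N x R) and per-matrix coefficient
matrices H_k (R x N) minimising

    sum_k ||X_k - W H_k||_F^2  +  alpha * (||W||_F^2 + sum_k ||H_k||_F^2)

subject to W >= 0, H_k >= 0.  W captures group-level connectivity structure;
the H_k carry the individual variation used as node features downstream.

The solver is a Lee-Seung-style multiplicative scheme extended to the shared
basis and the Tikhonov (squared-Frobenius) penalty:

    W   <- W  * (sum_k X_k H_k^T) / (W sum_k H_k H_k^T + alpha W + eps)
    H_k <- H_k * (W^T X_k)        / (W^T W H_k + alpha H_k + eps)

which keeps all factors non-negative and never increases the objective.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .connectivity import ConnectivityMatrix

__all__ = ["JointNMF", "jnmf_objective", "multiplicative_step", "subject_node_features"]

_EPS = 1e-10


def _as_arrays(X) -> tuple[list, list[np.ndarray]]:
    """Normalise input to (keys, list of ndarray); accepts dict, list, matrices."""
    if isinstance(X, dict):
        keys = list(X.keys())
        mats = [X[k] for k in keys]
    else:
        mats = list(X)
        keys = list(range(len(mats)))
    arrays = []
    for key, m in zip(keys, mats):
        a = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
        if a.min() < 0:
            raise ValueError(
                f"matrix {key!r} has negative entries; apply threshold_positive first"
            )
        arrays.append(np.asarray(a, dtype=float))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {sorted(shapes)}")
    return keys, arrays


def jnmf_objective(X_list, W: np.ndarray, H_list, alpha: float) -> float:
    """Regularised joint reconstruction objective (see module docstring)."""
    _, arrays = _as_arrays(X_list)
    H_list = [np.asarray(h, float) for h in H_list]
    if len(H_list) != len(arrays):
        raise ValueError(f"{len(arrays)} matrices but {len(H_list)} coefficient blocks")
    total = alpha * float(np.sum(W * W))
    for k, (x, h) in enumerate(zip(arrays, H_list)):
        if W.shape[0] != x.shape[0] or h.shape != (W.shape[1], x.shape[1]):
            raise ValueError(f"shape mismatch for matrix index {k}")
        r = x - W @ h
        total += float(np.sum(r * r)) + alpha * float(np.sum(h * h))
    return total


def multiplicative_step(X: np.ndarray, W: np.ndarray, H: np.ndarray, alpha: float):
    """One synchronized multiplicative update: W first, then every H_k.

    X is (K, N, M) stacked, H is (K, R, M). Returns new (W, H); inputs unchanged.
    """
    num_w = np.einsum("knm,krm->nr", X, H)
    hht = np.einsum("krm,ksm->rs", H, H)
    W = W * num_w / (W @ hht + alpha * W + _EPS)
    wtw = W.T @ W
    num_h = np.einsum("nr,knm->krm", W, X)
    H = H * num_h / (np.einsum("rs,ksm->krm", wtw, H) + alpha * H + _EPS)
    return W, H


def subject_node_features(W, H: dict, subject_id, task_ids, mode: str = "H") -> np.ndarray:
    """Per-node feature matrix for one subject, concatenated over tasks.

    mode "H": node i gets column i of H_(s,k) -> N x (R*K) features.
    mode "WH": node i gets row i of the reconstruction W @ H_(s,k) -> N x (N*K).
    """
    blocks = []
    for t in task_ids:
        key = (subject_id, t)
        if key not in H:
            raise KeyError(f"no coefficients for {key!r}")
        h = np.asarray(H[key], float)
        if mode == "H":
            blocks.append(h.T)
        elif mode == "WH":
            blocks.append(np.asarray(W, float) @ h)
        else:
            raise ValueError(f"unknown feature mode {mode!r}")
    return np.concatenate(blocks, axis=1)


class JointNMF(BaseEstimator):
    """Shared-basis joint NMF solved by multiplicative updates.

    Parameters
    ----------
    rank : int
        Number of latent factors R (default 5).
    alpha : float
        Weight of the squared-Frobenius penalty on W and every H_k
        (default 0.1).
    max_iters : int
        Iteration cap T.
    tol : float
        Stop when the relative objective decrease falls below this.
    seed : int
        Seed for the uniform initialisation.

    Attributes
    ----------
    W_ : (N, R) ndarray, shared non-negative basis.
    H_ : dict mapping input key -> (R, N) non-negative coefficients.
    objective_trace_ : list of objective values (initial value first, then
        one entry per iteration); non-increasing.
    n_iter_ : iterations actually run.
    """

    def __init__(self, rank: int = 5, alpha: float = 0.1, max_iters: int = 500,
                 tol: float = 1e-7, seed: int = 0):
        self.rank = rank
        self.alpha = alpha
        self.max_iters = max_iters
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None) -> "JointNMF":
        keys, arrays = _as_arrays(X)
        n, m = arrays[0].shape
        if not 1 <= self.rank <= n:
            raise ValueError(f"rank must be in [1, {n}], got {self.rank}")
        if self.alpha < 0 or self.tol < 0 or self.max_iters < 1:
            raise ValueError("alpha >= 0, tol >= 0 and max_iters >= 1 required")
        stacked = np.stack(arrays)  # (K, N, M)
        rng = np.random.default_rng(self.seed)
        scale = np.sqrt(max(stacked.mean(), _EPS) / self.rank)
        W = rng.uniform(0, 1, size=(n, self.rank)) * scale
        # one shared H init replicated over k: the H_k subproblems are
        # independent given W, so identical inputs evolve identically
        h0 = rng.uniform(0, 1, size=(self.rank, m)) * scale
        H = np.repeat(h0[None, :, :], len(arrays), axis=0)

        trace = [jnmf_objective(arrays, W, list(H), self.alpha)]
        for _ in range(self.max_iters):
            W, H = multiplicative_step(stacked, W, H, self.alpha)
            obj = jnmf_objective(arrays, W, list(H), self.alpha)
            prev = trace[-1]
            trace.append(obj)
            if prev > 0 and (prev - obj) / prev < self.tol:
                break
        self.keys_ = keys
        self.W_ = W
        self.H_ = {k: H[i] for i, k in enumerate(keys)}
        self.objective_trace_ = trace
        self.n_iter_ = len(trace) - 1
        self.reconstruction_err_ = float(
            np.sqrt(sum(np.sum((x - W @ self.H_[k]) ** 2)
                        for k, x in zip(keys, arrays)))
        )
        return self

    def transform(self, subject_id, task_ids, mode: str = "H") -> np.ndarray:
        """Node-feature matrix for one subject (see `subject_node_features`)."""
        return subject_node_features(self.W_, self.H_, subject_id, task_ids, mode)

    def coefficients_for(self, X, n_iters: int = 200) -> dict:
        """Coefficients H for new matrices with the basis W_ held fixed.

        Runs the H-side multiplicative update only; used to project held-out
        subjects onto the basis learned on the training split.
        """
        keys, arrays = _as_arrays(X)
        W = self.W_
        wtw = W.T @ W
        rng = np.random.default_rng(self.seed + 1)
        out = {}
        for key, x in zip(keys, arrays):
            h = rng.uniform(0, 1, size=(W.shape[1], x.shape[1])) * np.sqrt(
                max(x.mean(), _EPS) / W.shape[1]
            )
            wtx = W.T @ x
            for _ in range(n_iters):
                h = h * wtx / (wtw @ h + self.alpha * h + _EPS)
            out[key] = h
        return out

    # -- serialization: delimited matrices + JSON manifest -------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "W.tsv", self.W_, delimiter="\t")
        key_names = []
        for i, k in enumerate(self.keys_):
            np.savetxt(d / f"H_{i}.tsv", self.H_[k], delimiter="\t")
            key_names.append(list(k) if isinstance(k, tuple) else k)
        manifest = {
            "rank": self.rank, "alpha": self.alpha, "seed": self.seed,
            "n_iter": self.n_iter_, "final_objective": self.objective_trace_[-1],
            "keys": key_names,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "JointNMF":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        est = cls(rank=manifest["rank"], alpha=manifest["alpha"], seed=manifest["seed"])
        est.W_ = np.loadtxt(d / "W.tsv", delimiter="\t", ndmin=2)
        est.keys_ = [tuple(k) if isinstance(k, list) else k for k in manifest["keys"]]
        est.H_ = {
            k: np.loadtxt(d / f"H_{i}.tsv", delimiter="\t", ndmin=2)
            for i, k in enumerate(est.keys_)
        }
        est.n_iter_ = manifest["n_iter"]
        est.objective_trace_ = [manifest["final_objective"]]
        return est
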