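"""Age regression from multi-task connectomes: joint NMF features + attention layers.

The predictor runs in two stages.  Stage 1 factorizes all training
connectivity matrices jointly (shared non-negative basis W, per-subject-task
coefficients H_k); the H_k columns become individualized node features.
Stage 2 trains a two-layer graph attention stack followed by a two-layer
fully connected regression head with Adam, minimising

    L = L_recon  +  lambda * sum_i sum_{j in N(i)} alpha_ij ||h_i - h_j||^2
                 +  mu * MSE(y_hat, y)

where L_recon is the (fixed) factorization objective, the middle term is a
graph-smoothness penalty on the final node embeddings, and the last term is
the age-prediction loss.  The factorization is solved by multiplicative
updates before gradient training starts, which preserves non-negativity that
gradient steps would violate; its objective enters the reported per-epoch
loss as a constant.

Two wirings are available for the two tasks: "branch" (default) gives every
task its own attention stack and merges the flattened embeddings through the
activation before the head; "concat" runs a single stack on features
concatenated across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Adam, Tensor
from .connectivity import ConnectivityMatrix
from .data import CohortData
from .gat import GATLayer
from .graph import BrainGraph, build_graph
from .jnmf import JointNMF

__all__ = [
    "ConnectomeGATRegressor",
    "TrainConfig",
    "smoothness_penalty",
    "prediction_loss",
    "combined_loss",
    "train",
    "predict_cohort",
]


# ---------------------------------------------------------------------------
# Loss functionals (numpy surface; the trainer uses autodiff equivalents)

def smoothness_penalty(embeddings: np.ndarray, graph: BrainGraph, attention) -> float:
    """sum_i sum_{j in N(i)} alpha_ij * ||h_i - h_j||^2 (squared Euclidean)."""
    h = np.asarray(embeddings, dtype=float)
    if h.shape[0] != graph.n_nodes:
        raise ValueError("embeddings rows must equal graph nodes")
    total = 0.0
    for i in range(graph.n_nodes):
        if isinstance(attention, dict):
            coeffs = attention.get(i, {})
        elif isinstance(attention, list):
            coeffs = attention[i]
        else:
            coeffs = attention(i)
        for j, a in coeffs.items():
            d = h[i] - h[j]
            total += float(a) * float(d @ d)
    return total


def prediction_loss(y_hat, y) -> float:
    """Mean squared error between predicted and actual ages."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty target vector")
    if y_hat.size != y.size:
        raise ValueError(f"length mismatch: {y_hat.size} vs {y.size}")
    return float(np.mean((y_hat - y) ** 2))


def combined_loss(
    X_list, W, H_list, embeddings, graph, attention, y_hat, y,
    alpha: float, lambda_smooth: float, mu_pred: float,
) -> tuple[float, dict]:
    """Total objective and its components (reconstruction, smoothness, prediction)."""
    from .jnmf import jnmf_objective

    recon = jnmf_objective(X_list, W, H_list, alpha)
    smooth = smoothness_penalty(embeddings, graph, attention)
    pred = prediction_loss(y_hat, y)
    total = recon + lambda_smooth * smooth + mu_pred * pred
    return total, {"reconstruction": recon, "smoothness": smooth, "prediction": pred}


@dataclass
class TrainConfig:
    """Gradient-training hyperparameters (config-file surface for the CLI)."""

    learning_rate: float = 1e-5
    optimizer: str = "adam"
    epochs: int = 6000
    weight_decay: float = 0.2
    lambda_smooth: float = 0.1
    mu_pred: float = 1.0
    hidden_dim: int = 8
    head_hidden: int = 100
    activation: str = "leaky_relu"
    seed: int = 0
    tasks: list = field(default_factory=list)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate > 0 and epochs >= 1 required")
        if self.lambda_smooth < 0 or self.mu_pred < 0:
            raise ValueError("lambda and mu must be non-negative")


class ConnectomeGATRegressor(BaseEstimator):
    """Two attention layers + two dense layers predicting age from connectomes.

    Parameters (selection)
    ----------
    rank, nmf_alpha, nmf_iters : stage-1 factorization settings.
    feature_mode : "H" (coefficient columns, default), "WH" (reconstruction
        rows) or "fc" (raw connectivity rows; the no-factorization ablation arm).
    branch_mode : "branch" (per-task stacks, default) or "concat".
    topology : "group" (one graph from the mean training connectivity per
        task, default) or "subject" (a graph per subject).
    attention : False replaces attention with uniform neighbor weights (the
        attention-free comparator).
    learning_rate, epochs, weight_decay : Adam settings (defaults 1e-5, 6000,
        0.2).
    lambda_smooth, mu_pred : weights of the smoothness and prediction terms.

    Attributes
    ----------
    jnmf_ : fitted JointNMF; loss_history_ : per-epoch component dict;
    layers_ : per-branch [layer1, layer2]; head_ : dense parameters.
    """

    def __init__(
        self,
        rank: int = 5,
        nmf_alpha: float = 0.1,
        nmf_iters: int = 300,
        feature_mode: str = "H",
        branch_mode: str = "branch",
        topology: str = "group",
        density: float = 0.10,
        self_loops: bool = True,
        attention: bool = True,
        hidden_dim: int = 8,
        head_hidden: int = 100,
        activation: str = "leaky_relu",
        leaky_slope: float = 0.2,
        learning_rate: float = 1e-5,
        epochs: int = 6000,
        weight_decay: float = 0.2,
        lambda_smooth: float = 0.1,
        mu_pred: float = 1.0,
        refit_h_every: int = 0,
        weighted_logits: bool = False,
        seed: int = 0,
    ):
        self.rank = rank
        self.nmf_alpha = nmf_alpha
        self.nmf_iters = nmf_iters
        self.feature_mode = feature_mode
        self.branch_mode = branch_mode
        self.topology = topology
        self.density = density
        self.self_loops = self_loops
        self.attention = attention
        self.hidden_dim = hidden_dim
        self.head_hidden = head_hidden
        self.activation = activation
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.lambda_smooth = lambda_smooth
        self.mu_pred = mu_pred
        self.refit_h_every = refit_h_every
        self.weighted_logits = weighted_logits
        self.seed = seed

    # -- feature & graph assembly -------------------------------------------

    def _fit_factorization(self, data: CohortData, train_subjects) -> None:
        if self.feature_mode == "fc":
            self.jnmf_ = None
            self.recon_term_ = 0.0
            return
        train_X = {
            (s, t): data.X[(s, t)] for s in train_subjects for t in data.tasks
        }
        self.jnmf_ = JointNMF(
            rank=self.rank, alpha=self.nmf_alpha, max_iters=self.nmf_iters,
            tol=1e-8, seed=self.seed,
        ).fit(train_X)
        self.recon_term_ = float(self.jnmf_.objective_trace_[-1])
        held_out = [s for s in data.subjects if s not in set(train_subjects)]
        if held_out:
            extra = {
                (s, t): data.X[(s, t)] for s in held_out for t in data.tasks
            }
            self.jnmf_.H_.update(self.jnmf_.coefficients_for(extra))

    def _subject_features(self, data: CohortData, subject) -> list[np.ndarray]:
        """Per-branch (N, F) feature blocks for one subject."""
        blocks = []
        for t in data.tasks:
            if self.feature_mode == "fc":
                m = data.fc[(subject, t)]
                blocks.append(m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m))
            else:
                blocks.append(
                    self.jnmf_.transform(subject, [t], mode=self.feature_mode)
                )
        if self.branch_mode == "concat":
            return [np.concatenate(blocks, axis=1)]
        return blocks

    def _branch_tasks(self, data: CohortData) -> list:
        return ["+".join(map(str, data.tasks))] if self.branch_mode == "concat" else list(data.tasks)

    def _build_topology(self, data: CohortData, train_subjects) -> None:
        """Graphs per branch: group-mean connectivity or per-subject."""
        self.graphs_ = {}
        n = data.n_rois
        dummy = np.zeros((n, 1))

        def _mean_fc(subjects, tasks):
            mats = [np.asarray(data.fc[(s, t)].values if isinstance(data.fc[(s, t)], ConnectivityMatrix)
                               else data.fc[(s, t)]) for s in subjects for t in tasks]
            return np.mean(mats, axis=0)

        branch_tasklists = (
            [list(data.tasks)] if self.branch_mode == "concat" else [[t] for t in data.tasks]
        )
        for bname, tl in zip(self._branch_tasks(data), branch_tasklists):
            if self.topology == "group":
                g = build_graph(_mean_fc(train_subjects, tl), dummy,
                                density=self.density, self_loops=self.self_loops)
                self.graphs_[bname] = g
            elif self.topology == "subject":
                self.graphs_[bname] = {
                    s: build_graph(_mean_fc([s], tl), dummy,
                                   density=self.density, self_loops=self.self_loops)
                    for s in data.subjects
                }
            else:
                raise ValueError(f"unknown topology {self.topology!r}")

    def _edges_for(self, branch, subject):
        g = self.graphs_[branch]
        if isinstance(g, dict):
            g = g[subject]
        return g.directed_edge_arrays()

    def _batch_edges(self, data, branch, subjects):
        n = data.n_rois
        dsts, srcs = [], []
        for b, s in enumerate(subjects):
            dst, src = self._edges_for(branch, s)
            dsts.append(dst + b * n)
            srcs.append(src + b * n)
        return np.concatenate(dsts), np.concatenate(srcs)

    def _batch_edge_weights(self, data, branch, subjects):
        """Cosine edge weights per batched directed edge (self-loops get 1),
        floored at a small positive value; used only when weighted_logits."""
        ws = []
        for s in subjects:
            g = self.graphs_[branch]
            if isinstance(g, dict):
                g = g[s]
            dst, src = g.directed_edge_arrays()
            w = np.array([
                1.0 if i == j else max(g.edge_weight[(i, j)], 1e-6)
                for i, j in zip(dst, src)
            ])
            ws.append(w)
        return np.concatenate(ws)[:, None]

    # -- parameter initialisation -------------------------------------------

    def _init_params(self, feat_dims: list[int], n_rois: int, y_train) -> None:
        rng = np.random.default_rng(self.seed)
        mode = "attention" if self.attention else "uniform"
        self.layers_ = {}
        for bname, f in zip(self._branch_names_, feat_dims):
            l1 = GATLayer(f, self.hidden_dim, self.leaky_slope, self.activation, mode, rng)
            l2 = GATLayer(self.hidden_dim, self.hidden_dim, self.leaky_slope,
                          self.activation, mode, rng)
            self.layers_[bname] = [l1, l2]
        in_head = len(self._branch_names_) * n_rois * self.hidden_dim
        scale = np.sqrt(2.0 / (in_head + self.head_hidden))
        self.head_ = {
            "W1": Tensor(rng.normal(0, scale, size=(in_head, self.head_hidden)), requires_grad=True),
            "b1": Tensor(np.zeros((1, self.head_hidden)), requires_grad=True),
            "W2": Tensor(rng.normal(0, np.sqrt(2.0 / self.head_hidden),
                                    size=(self.head_hidden, 1)), requires_grad=True),
            "b2": Tensor(np.full((1, 1), float(np.mean(y_train))), requires_grad=True),
        }

    @property
    def parameters_(self) -> list[Tensor]:
        params = []
        for layers in self.layers_.values():
            for l in layers:
                params.extend(l.params)
        params.extend(self.head_.values())
        return params

    # -- forward -------------------------------------------------------------

    def _activate(self, x: Tensor) -> Tensor:
        return x.relu() if self.activation == "relu" else x.leaky_relu(self.leaky_slope)

    def _forward(self, data: CohortData, subjects, masks=None):
        """Batched forward pass.

        Returns (predictions (B,1) Tensor, smoothness Tensor scalar mean per
        subject). `masks`, if given, is a dict with per-branch edge gates
        ((E,1) Tensors aligned with the batched directed edges) and a
        feature gate dict per branch ((1,F) Tensor).
        """
        n = data.n_rois
        b_sz = len(subjects)
        branch_embeddings = []
        smooth_total = None
        for bi, bname in enumerate(self._branch_names_):
            feats = np.stack(
                [self._subject_features(data, s)[bi] for s in subjects]
            )  # (B, N, F)
            h = Tensor(feats.reshape(b_sz * n, -1) / self._feature_scale_[bname])
            if masks is not None and masks.get("feature") is not None:
                h = h * masks["feature"][bname]
            dst, src = self._batch_edges(data, bname, subjects)
            gate = None
            if self.weighted_logits:
                gate = Tensor(self._batch_edge_weights(data, bname, subjects))
            if masks is not None and masks.get("edge") is not None:
                m = masks["edge"][bname]
                gate = m if gate is None else gate * m
            l1, l2 = self.layers_[bname]
            h1, _, _ = l1.forward(h, dst, src, b_sz * n, edge_gate=gate)
            h2, alpha2, _ = l2.forward(h1, dst, src, b_sz * n, edge_gate=gate)
            diff = h2.gather(dst) - h2.gather(src)
            sm = ((diff * diff).sum(axis=1, keepdims=True) * alpha2).sum() * (1.0 / b_sz)
            smooth_total = sm if smooth_total is None else smooth_total + sm
            branch_embeddings.append(h2.reshape(b_sz, n * self.hidden_dim))
        merged = (
            branch_embeddings[0]
            if len(branch_embeddings) == 1
            else Tensor.concat(branch_embeddings, axis=1)
        )
        merged = self._activate(merged)  # merge embeddings across modalities
        z = self._activate(merged @ self.head_["W1"] + self.head_["b1"])
        pred = z @ self.head_["W2"] + self.head_["b2"]
        return pred, smooth_total

    # -- training ------------------------------------------------------------

    def fit(self, data: CohortData, train_idx=None, y=None) -> "ConnectomeGATRegressor":
        if train_idx is None:
            train_idx = np.arange(data.n_subjects)
        train_idx = np.asarray(train_idx, dtype=int)
        if train_idx.size == 0:
            raise ValueError("empty training split")
        if data.n_subjects < 2:
            raise ValueError("need at least 2 subjects with targets")
        train_subjects = [data.subjects[i] for i in train_idx]
        y_train = data.ages[train_idx]

        self._fit_factorization(data, train_subjects)
        self._branch_names_ = self._branch_tasks(data)
        self._build_topology(data, train_subjects)

        # feature scale: one scalar per branch from the training split,
        # keeping gradient magnitudes comparable across feature modes
        self._feature_scale_ = {}
        feat_dims = []
        for bi, bname in enumerate(self._branch_names_):
            sample = np.stack(
                [self._subject_features(data, s)[bi] for s in train_subjects]
            )
            sd = sample.std()
            self._feature_scale_[bname] = float(sd) if sd > 0 else 1.0
            feat_dims.append(sample.shape[-1])

        self._init_params(feat_dims, data.n_rois, y_train)
        opt = Adam(self.parameters_, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        y_t = Tensor(y_train.reshape(-1, 1))
        self.loss_history_ = []
        for epoch in range(self.epochs):
            if self.refit_h_every and epoch and epoch % self.refit_h_every == 0:
                keys = [(s, t) for s in train_subjects for t in data.tasks]
                self.jnmf_.H_.update(
                    self.jnmf_.coefficients_for({k: data.X[k] for k in keys}, n_iters=20)
                )
            pred, smooth = self._forward(data, train_subjects)
            resid = pred - y_t
            mse = (resid * resid).mean()
            loss = self.mu_pred * mse + self.lambda_smooth * smooth
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.loss_history_.append(
                {
                    "reconstruction": self.recon_term_,
                    "smoothness": float(smooth.data),
                    "prediction": float(mse.data),
                    "total": self.recon_term_
                    + self.lambda_smooth * float(smooth.data)
                    + self.mu_pred * float(mse.data),
                }
            )
        return self

    def predict(self, data: CohortData, idx=None) -> np.ndarray:
        if not hasattr(self, "layers_"):
            raise RuntimeError("model is not fitted")
        if idx is None:
            idx = np.arange(data.n_subjects)
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            return np.zeros(0)
        subjects = [data.subjects[i] for i in idx]
        if self.feature_mode != "fc":
            missing = [
                (s, t) for s in subjects for t in data.tasks
                if (s, t) not in self.jnmf_.H_
            ]
            if missing:
                self.jnmf_.H_.update(
                    self.jnmf_.coefficients_for({k: data.X[k] for k in missing})
                )
        preds = []
        for s in subjects:  # per-subject forward == batched forward (block-diagonal)
            p, _ = self._forward(data, [s])
            preds.append(float(p.data[0, 0]))
        return np.asarray(preds)

    # -- explainer hooks ------------------------------------------------------

    def explain_edge_pairs(self, data: CohortData, subject) -> list[tuple[int, int]]:
        """Undirected (i, j) pairs over the union of branch topologies."""
        pairs = set()
        for bname in self._branch_names_:
            g = self.graphs_[bname]
            if isinstance(g, dict):
                g = g[subject]
            pairs.update(g.undirected_edges)
        return sorted(pairs)

    def masked_forward(
        self, data: CohortData, subject, edge_gate: Tensor, feature_gate: Tensor
    ) -> Tensor:
        """Prediction for one subject with soft edge and feature masks applied.

        `edge_gate` is (n_pairs, 1) in [0,1] aligned with
        `explain_edge_pairs`; self-loops are never masked. `feature_gate` is
        (1, F_total) with F_total the per-branch feature dims summed.
        """
        pairs = self.explain_edge_pairs(data, subject)
        pair_pos = {p: k for k, p in enumerate(pairs)}
        gate_ext = Tensor.concat([edge_gate, Tensor(np.ones((1, 1)))], axis=0)
        edge_masks, feat_masks = {}, {}
        offset = 0
        for bi, bname in enumerate(self._branch_names_):
            dst, src = self._batch_edges(data, bname, [subject])
            idx = np.array(
                [pair_pos[(min(i, j), max(i, j))] if i != j else len(pairs)
                 for i, j in zip(dst, src)],
                dtype=np.intp,
            )
            edge_masks[bname] = gate_ext.gather(idx)
            f = self._subject_features(data, subject)[bi].shape[1]
            sel = np.arange(offset, offset + f, dtype=np.intp)
            feat_masks[bname] = feature_gate.T.gather(sel).T
            offset += f
        pred, _ = self._forward(
            data, [subject], masks={"edge": edge_masks, "feature": feat_masks}
        )
        return pred


def train(dataset: CohortData, jnmf_config: dict | None = None,
          train_config: TrainConfig | dict | None = None,
          train_idx=None) -> ConnectomeGATRegressor:
    """Thin functional wrapper assembling the estimator from config blocks."""
    jn = dict(jnmf_config or {})
    tc = train_config if isinstance(train_config, dict) else (
        vars(train_config).copy() if train_config else {})
    tc.pop("tasks", None)
    tc.pop("optimizer", None)
    est = ConnectomeGATRegressor(
        rank=jn.get("rank", 5), nmf_alpha=jn.get("alpha", 0.1),
        nmf_iters=jn.get("max_iters", 300), **tc,
    )
    return est.fit(dataset, train_idx=train_idx)


def predict_cohort(model: ConnectomeGATRegressor, data: CohortData, idx=None) -> np.ndarray:
    """One predicted age per requested subject, order-preserving."""
    return model.predict(data, idx=idx)
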