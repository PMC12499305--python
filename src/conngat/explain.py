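"""Post-hoc interpretation: learned edge and feature masks over the predictor.

Soft masks in [0,1] are parameterized through a sigmoid and optimized by
gradient descent so that the masked model reproduces its own unmasked
prediction (a mutual-information-motivated objective) while sparsity and
entropy terms shrink and binarize the masks.  Five weighted loss components
drive the optimization: prediction loss, feature size loss, feature element
loss, population (edge) size loss and population element loss.  Size losses
are mean mask values; element losses are mean binary entropies, which vanish
as mask entries saturate at 0 or 1.

The prediction loss is the squared error of the masked prediction against
the model's own unmasked prediction — the regression analogue of the usual
cross-entropy, so the explanation is faithful to the model rather than to
the label.

Edge masks multiply the attention softmax numerators (a masked edge has its
coefficient suppressed before renormalization); feature masks multiply the
node-feature columns.  Self-loops are never masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .atlas import RoiAtlas

__all__ = [
    "ExplainerConfig",
    "ExplanationMask",
    "GNNExplainer",
    "explainer_losses",
    "explain_subject",
    "common_connections",
    "stagewise_common_connections",
    "network_tabulation",
]


@dataclass
class ExplainerConfig:
    """Loss weights and optimizer settings for mask learning."""

    pred_loss_w: float = 1.0
    feat_size_w: float = 200.0
    feat_elem_w: float = 20.0
    pop_size_w: float = 0.0
    pop_elem_w: float = 1000.0
    weight_decay: float = 0.0
    epochs: int = 150
    learning_rate: float = 0.5

    def __post_init__(self):
        weights = (self.pred_loss_w, self.feat_size_w, self.feat_elem_w,
                   self.pop_size_w, self.pop_elem_w, self.weight_decay)
        if any(w < 0 for w in weights):
            raise ValueError("loss weights must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ExplanationMask:
    """Per-edge and per-feature importances for one subject.

    edge_mask maps both (i, j) and (j, i) to the same value in [0, 1];
    feature_mask is a length-F vector in [0, 1].
    """

    edge_mask: dict
    feature_mask: np.ndarray
    objective_trace: list = field(default_factory=list)
    subject_id: object = None

    def __post_init__(self):
        vals = np.array(list(self.edge_mask.values()) , dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("edge mask values must lie in [0, 1]")
        self.feature_mask = np.asarray(self.feature_mask, dtype=float)
        if self.feature_mask.size and (
            self.feature_mask.min() < 0 or self.feature_mask.max() > 1
        ):
            raise ValueError("feature mask values must lie in [0, 1]")
        sym = {}
        for (i, j), v in self.edge_mask.items():
            sym[(i, j)] = v
            sym[(j, i)] = v
        self.edge_mask = sym

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted({(min(i, j), max(i, j)) for i, j in self.edge_mask})

    def pair_values(self) -> np.ndarray:
        return np.array([self.edge_mask[p] for p in self.pairs])


def _entropy_mean(m: np.ndarray) -> float:
    m = np.clip(m, 1e-12, 1 - 1e-12)
    return float(np.mean(-m * np.log(m) - (1 - m) * np.log(1 - m)))


def explainer_losses(model, data, subject, masks: ExplanationMask,
                     config: ExplainerConfig | None = None) -> dict:
    """Weighted loss components for given masks (numpy evaluation surface)."""
    config = config or ExplainerConfig()
    edge_vals = masks.pair_values()
    feat_vals = masks.feature_mask
    if edge_vals.size and (edge_vals.min() < 0 or edge_vals.max() > 1):
        raise ValueError("edge mask outside [0, 1]")
    pairs = model.explain_edge_pairs(data, subject)
    gate = Tensor(np.array([[masks.edge_mask[p]] for p in pairs]))
    fgate = Tensor(feat_vals.reshape(1, -1))
    masked = float(model.masked_forward(data, subject, gate, fgate).data)
    ref = float(
        model.masked_forward(
            data, subject,
            Tensor(np.ones((len(pairs), 1))), Tensor(np.ones((1, feat_vals.size))),
        ).data
    )
    comp = {
        "prediction": (masked - ref) ** 2,
        "feat_size": float(np.mean(feat_vals)) if feat_vals.size else 0.0,
        "feat_elem": _entropy_mean(feat_vals) if feat_vals.size else 0.0,
        "pop_size": float(np.mean(edge_vals)) if edge_vals.size else 0.0,
        "pop_elem": _entropy_mean(edge_vals) if edge_vals.size else 0.0,
    }
    comp["total"] = (
        config.pred_loss_w * comp["prediction"]
        + config.feat_size_w * comp["feat_size"]
        + config.feat_elem_w * comp["feat_elem"]
        + config.pop_size_w * comp["pop_size"]
        + config.pop_elem_w * comp["pop_elem"]
    )
    return comp


class GNNExplainer:
    """Learns the masks for one subject at a time via Adam on sigmoid logits."""

    def __init__(self, config: ExplainerConfig | None = None, seed: int = 0):
        self.config = config or ExplainerConfig()
        self.seed = seed

    def explain(self, model, data, subject) -> ExplanationMask:
        cfg = self.config
        pairs = model.explain_edge_pairs(data, subject)
        n_feat = sum(
            blk.shape[1] for blk in model._subject_features(data, subject)
        ) if hasattr(model, "_subject_features") else model.n_features_
        rng = np.random.default_rng(self.seed)
        # zero-mean init puts masks at the entropy saddle (0.5); the prediction
        # term then decides which edges/features escape toward 1
        e_logit = Tensor(rng.normal(0.0, 0.1, size=(len(pairs), 1)), requires_grad=True)
        f_logit = Tensor(rng.normal(0.0, 0.1, size=(1, n_feat)), requires_grad=True)
        ones_e = Tensor(np.ones((len(pairs), 1)))
        ones_f = Tensor(np.ones((1, n_feat)))
        ref = model.masked_forward(data, subject, ones_e, ones_f).detach()
        opt = Adam([e_logit, f_logit], lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        trace = []
        for epoch in range(cfg.epochs):
            # tiny clamp keeps the entropy logs finite once masks saturate
            em = e_logit.sigmoid() * (1 - 2e-9) + 1e-9
            fm = f_logit.sigmoid() * (1 - 2e-9) + 1e-9
            pred = model.masked_forward(data, subject, em, fm)
            d = pred - ref
            pred_loss = (d * d).sum()
            loss = cfg.pred_loss_w * pred_loss
            comp = {"prediction": float(pred_loss.data)}
            if n_feat:
                fs = fm.mean()
                fe = (-(fm * fm.log()) - (1.0 - fm) * (1.0 - fm).log()).mean()
                loss = loss + cfg.feat_size_w * fs + cfg.feat_elem_w * fe
                comp["feat_size"] = float(fs.data)
                comp["feat_elem"] = float(fe.data)
            if len(pairs):
                ps = em.mean()
                pe = (-(em * em.log()) - (1.0 - em) * (1.0 - em).log()).mean()
                loss = loss + cfg.pop_size_w * ps + cfg.pop_elem_w * pe
                comp["pop_size"] = float(ps.data)
                comp["pop_elem"] = float(pe.data)
            comp["total"] = float(loss.data)
            if not np.isfinite(comp["total"]):
                raise RuntimeError(f"non-finite explainer objective at epoch {epoch}")
            trace.append(comp)
            opt.zero_grad()
            loss.backward()
            opt.step()
        edge_vals = 1.0 / (1.0 + np.exp(-e_logit.data.ravel()))
        feat_vals = 1.0 / (1.0 + np.exp(-f_logit.data.ravel()))
        return ExplanationMask(
            edge_mask={p: float(v) for p, v in zip(pairs, edge_vals)},
            feature_mask=feat_vals,
            objective_trace=trace,
            subject_id=subject,
        )


def explain_subject(model, data, subject, config: ExplainerConfig | None = None,
                    seed: int = 0) -> ExplanationMask:
    """Functional wrapper over `GNNExplainer.explain`."""
    return GNNExplainer(config=config, seed=seed).explain(model, data, subject)


def common_connections(masks: list[ExplanationMask], fraction: float,
                       atlas: RoiAtlas | None = None) -> pd.DataFrame:
    """Edges most consistently important across subjects.

    Per subject, the top `fraction` of that subject's edges by mask value are
    marked; each edge's frequency is the share of subjects marking it.  Edges
    are ranked by (frequency, mean mask weight, lexicographic) and the table
    is truncated to the top `fraction` of all edges.  ROI columns are
    1-based.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    universe = masks[0].pairs
    uni_set = set(universe)
    for m in masks[1:]:
        if set(m.pairs) != uni_set:
            raise ValueError("masks cover inconsistent node-pair sets")
    k = math.ceil(fraction * len(universe))
    freq = {p: 0 for p in universe}
    for m in masks:
        order = sorted(universe, key=lambda p: (-m.edge_mask[p], p))
        for p in order[:k]:
            freq[p] += 1
    n_subj = len(masks)
    mean_w = {p: float(np.mean([m.edge_mask[p] for m in masks])) for p in universe}
    ranked = sorted(universe, key=lambda p: (-freq[p] / n_subj, -mean_w[p], p))[:k]
    rows = []
    for i, j in ranked:
        rows.append(
            {
                "roi_i": i + 1,
                "roi_j": j + 1,
                "network_i": atlas.network_of(i + 1) if atlas else "UNK",
                "network_j": atlas.network_of(j + 1) if atlas else "UNK",
                "frequency": freq[(i, j)] / n_subj,
                "mean_weight": mean_w[(i, j)],
            }
        )
    return pd.DataFrame(rows, columns=["roi_i", "roi_j", "network_i", "network_j",
                                       "frequency", "mean_weight"])


def stagewise_common_connections(
    masks: list[ExplanationMask], ages, stage_edges, fraction: float,
    atlas: RoiAtlas | None = None,
) -> dict:
    """Common-connection tables per developmental stage.

    Subjects are grouped by `stage_edges` (bin boundaries over age; stage s
    holds ages in [edge_s, edge_{s+1}), last bin right-inclusive) and the
    common-connection ranking runs within each group.  Stage boundaries are
    a caller input since no canonical values exist.  Empty stages are
    omitted.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(masks):
        raise ValueError("one age per mask required")
    edges = np.asarray(stage_edges, dtype=float)
    out = {}
    for s in range(len(edges) - 1):
        lo, hi = edges[s], edges[s + 1]
        if s == len(edges) - 2:
            members = [m for m, a in zip(masks, ages) if lo <= a <= hi]
        else:
            members = [m for m, a in zip(masks, ages) if lo <= a < hi]
        if members:
            out[(float(lo), float(hi))] = common_connections(
                members, fraction, atlas=atlas
            )
    return out


def network_tabulation(table: pd.DataFrame, atlas: RoiAtlas) -> pd.DataFrame:
    """Symmetric network-by-network matrix of connection counts.

    Diagonal entries count intra-network connections; the upper triangle plus
    diagonal sums to the number of table rows.
    """
    nets = sorted(set(atlas.network_label))
    counts = pd.DataFrame(0, index=nets, columns=nets, dtype=int)
    for _, row in table.iterrows():
        a = atlas.network_of(int(row["roi_i"]))
        b = atlas.network_of(int(row["roi_j"]))
        if a == b:
            counts.loc[a, a] += 1
        else:
            counts.loc[a, b] += 1
            counts.loc[b, a] += 1
    return counts
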