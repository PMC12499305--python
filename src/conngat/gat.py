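"""Graph attention layer, written from scratch on the package autodiff engine.

For node i with neighbors N(i), the attention logit toward neighbor j is

    e_ij = LeakyReLU( a^T [W h_i || W h_j] )

with a learnable linear map W (F' x F) and attention vector a (length 2F').
Logits are softmax-normalised over N(i) (with max-subtraction for overflow
safety) and the output is the attention-weighted sum of transformed neighbor
features passed through an activation:

    h'_i = sigma( sum_{j in N(i)} alpha_ij W h_j ).

Edge cosine weights select the topology only; they do not enter the logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .graph import BrainGraph

__all__ = [
    "GatLayerParams",
    "GATLayer",
    "attention_logits",
    "attention_coefficients",
    "gat_layer_forward",
]


@dataclass
class GatLayerParams:
    """Learnable parameters of one attention layer.

    W_lin is F' x F (output by input); a_vec has length 2F', split as
    [a_self, a_neighbor].
    """

    W_lin: np.ndarray
    a_vec: np.ndarray
    leaky_slope: float = 0.2

    def __post_init__(self):
        self.W_lin = np.asarray(self.W_lin, dtype=float)
        self.a_vec = np.asarray(self.a_vec, dtype=float).ravel()
        if self.W_lin.ndim != 2:
            raise ValueError("W_lin must be a 2-D matrix")
        if not (np.isfinite(self.W_lin).all() and np.isfinite(self.a_vec).all()):
            raise ValueError("parameters must be finite")
        if self.a_vec.size != 2 * self.W_lin.shape[0]:
            raise ValueError(
                f"a_vec length {self.a_vec.size} != 2*F' = {2 * self.W_lin.shape[0]}"
            )

    @property
    def out_dim(self) -> int:
        return self.W_lin.shape[0]

    @property
    def in_dim(self) -> int:
        return self.W_lin.shape[1]


def _neighborhood(graph: BrainGraph, i: int) -> list[int]:
    nb = sorted(graph.neighbors[i])
    if graph.self_loops:
        nb.append(i)
    return nb


def attention_logits(graph: BrainGraph, params: GatLayerParams, i: int, j: int) -> float:
    """Raw logit e_ij for one (node, neighbor) pair."""
    if j not in set(_neighborhood(graph, i)):
        raise ValueError(f"node {j} is not in the neighborhood of node {i}")
    f_prime = params.out_dim
    zi = params.W_lin @ graph.node_features[i]
    zj = params.W_lin @ graph.node_features[j]
    pre = params.a_vec[:f_prime] @ zi + params.a_vec[f_prime:] @ zj
    return float(pre if pre > 0 else params.leaky_slope * pre)


def attention_coefficients(
    graph: BrainGraph, params: GatLayerParams, i: int
) -> dict[int, float]:
    """Softmax-normalised coefficients alpha_ij over the neighborhood of i."""
    nb = _neighborhood(graph, i)
    if not nb:
        raise ValueError(
            f"node {i} has no neighbors; enable self-loops or increase graph density"
        )
    logits = np.array([attention_logits(graph, params, i, j) for j in nb])
    ex = np.exp(logits - logits.max())
    alpha = ex / ex.sum()
    return {j: float(a) for j, a in zip(nb, alpha)}


def gat_layer_forward(
    graph: BrainGraph, params: GatLayerParams, activation: str = "leaky_relu"
) -> np.ndarray:
    """Full-layer forward pass returning the N x F' output feature matrix."""
    layer = GATLayer.from_params(params, activation=activation)
    dst, src = graph.directed_edge_arrays()
    if len(np.unique(dst)) != graph.n_nodes:
        missing = sorted(set(range(graph.n_nodes)) - set(dst.tolist()))
        raise ValueError(
            f"node(s) {missing} have empty neighborhoods; enable self-loops"
        )
    out, _, _ = layer.forward(Tensor(graph.node_features), dst, src, graph.n_nodes)
    return out.data


class GATLayer:
    """Vectorised attention layer over explicit directed edge arrays.

    Operates on a stacked node-feature tensor (possibly many disjoint subject
    graphs batched block-diagonally).  `mode="uniform"` replaces attention
    with equal neighbor weights (the attention-free comparator arm).
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        leaky_slope: float = 0.2,
        activation: str = "leaky_relu",
        mode: str = "attention",
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.W = Tensor(rng.normal(0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.a_self = Tensor(rng.normal(0, scale, size=(out_dim, 1)), requires_grad=True)
        self.a_nbr = Tensor(rng.normal(0, scale, size=(out_dim, 1)), requires_grad=True)
        self.leaky_slope = leaky_slope
        self.activation = activation
        self.mode = mode

    @classmethod
    def from_params(cls, params: GatLayerParams, activation: str = "leaky_relu") -> "GATLayer":
        layer = cls(params.in_dim, params.out_dim, leaky_slope=params.leaky_slope,
                    activation=activation)
        layer.W = Tensor(params.W_lin.T, requires_grad=True)
        f = params.out_dim
        layer.a_self = Tensor(params.a_vec[:f].reshape(-1, 1), requires_grad=True)
        layer.a_nbr = Tensor(params.a_vec[f:].reshape(-1, 1), requires_grad=True)
        return layer

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.a_self, self.a_nbr]

    def to_layer_params(self) -> GatLayerParams:
        return GatLayerParams(
            W_lin=self.W.data.T,
            a_vec=np.concatenate([self.a_self.data.ravel(), self.a_nbr.data.ravel()]),
            leaky_slope=self.leaky_slope,
        )

    def _activate(self, x: Tensor) -> Tensor:
        if self.activation == "leaky_relu":
            return x.leaky_relu(self.leaky_slope)
        if self.activation == "relu":
            return x.relu()
        if self.activation == "linear":
            return x
        raise ValueError(f"unknown activation {self.activation!r}")

    def forward(
        self,
        h: Tensor,
        dst: np.ndarray,
        src: np.ndarray,
        n_nodes: int,
        edge_gate: Tensor | None = None,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (output (n_nodes, F'), alpha (E, 1), logits (E, 1)).

        dst[e] is the aggregating node i, src[e] the attended neighbor j.
        `edge_gate` (E, 1), if given, multiplies the softmax numerators before
        renormalisation (soft edge masking).
        """
        z = h @ self.W  # (M, F')
        if self.mode == "uniform":
            logits = Tensor(np.zeros((len(dst), 1)))
        else:
            pre = z.gather(dst) @ self.a_self + z.gather(src) @ self.a_nbr
            logits = pre.leaky_relu(self.leaky_slope)
        # max-subtraction per destination group; a constant shift, exact gradient
        group_max = np.full(n_nodes, -np.inf)
        np.maximum.at(group_max, dst, logits.data.ravel())
        group_max[~np.isfinite(group_max)] = 0.0
        ex = (logits - Tensor(group_max[dst][:, None])).exp()
        if edge_gate is not None:
            ex = ex * edge_gate
        denom = ex.segment_sum(dst, n_nodes).gather(dst)
        alpha = ex / (denom + 1e-30)
        out = (alpha * z.gather(src)).segment_sum(dst, n_nodes)
        return self._activate(out), alpha, logits
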