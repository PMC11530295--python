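"""Geometric vector perceptrons and the equivariant message-passing trunk.

A GVP jointly transforms rotation-invariant scalar channels and
rotation-equivariant 3-vector channels.  Vectors pass through two bias-free
channel-mixing linears; their norms after the first linear feed the scalar
path, and a nonnegative gate on the norms after the second modulates the
output vectors:

    V' = sigma+(|| W_mu W_h V ||_2) (*) (W_mu W_h V)
    s' = sigma( W_m [ || W_h V ||_2 , s ] + b )

Because every vector operation is either channel mixing or scaling by an
invariant, scalars are exactly rotation-invariant and vectors exactly
equivariant.  The trunk stacks message-passing layers in which a GVP stack
transforms [source node || edge] features into messages, mean-aggregated
into a residual LayerNorm update; a final vector-collapsing GVP yields the
L x D scalar feature map used for pooling and attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .nn import Module, Linear, VectorLinear, Dropout

__all__ = ["ScalarVector", "GVP", "SVLayerNorm", "GVPConv", "GVPBackbone",
           "GnnConfig"]


@dataclass
class ScalarVector:
    """Paired scalar (L, n_s) and vector (L, n_v, 3) features."""

    s: Tensor
    V: Tensor

    @property
    def widths(self) -> tuple:
        return self.s.shape[-1], self.V.shape[-2]

    def cat(self, other: "ScalarVector") -> "ScalarVector":
        return ScalarVector(concat([self.s, other.s], axis=-1),
                            concat([self.V, other.V], axis=-2))

    def gather(self, index: np.ndarray) -> "ScalarVector":
        return ScalarVector(self.s.gather(index), self.V.gather(index))

    def __add__(self, other: "ScalarVector") -> "ScalarVector":
        return ScalarVector(self.s + other.s, self.V + other.V)

    @staticmethod
    def from_arrays(s: np.ndarray, V: np.ndarray) -> "ScalarVector":
        return ScalarVector(Tensor(s), Tensor(V))


class GVP(Module):
    """One geometric vector perceptron.

    in_dims/out_dims are (scalar, vector) channel counts; `h_dim` is the
    intermediate vector width (defaults to max of in/out vector widths).
    `activations=False` turns off both nonlinearities (used as the last
    member of a message stack).  A vector output width of 0 collapses the
    geometry into scalars only.
    """

    def __init__(self, in_dims: tuple, out_dims: tuple, rng: np.random.Generator,
                 h_dim: int | None = None, activations: bool = True,
                 vector_gate: bool = True):
        si, vi = in_dims
        so, vo = out_dims
        self.in_dims, self.out_dims = (si, vi), (so, vo)
        self.h_dim = h_dim or max(vi, vo, 1)
        self.activations = activations
        self.vector_gate = vector_gate
        if vi > 0:
            self.W_h = VectorLinear(vi, self.h_dim, rng)
            self.W_m = Linear(self.h_dim + si, so, rng)
            if vo > 0:
                self.W_mu = VectorLinear(self.h_dim, vo, rng)
        else:
            self.W_m = Linear(si, so, rng)
            if vo > 0:
                raise ValueError("cannot produce vector outputs from scalar-only input")

    def __call__(self, x: ScalarVector) -> ScalarVector:
        si, vi = x.widths
        if (si, vi) != self.in_dims:
            raise ValueError(f"GVP input widths {(si, vi)} != declared {self.in_dims}")
        so, vo = self.out_dims
        if vi > 0:
            Vh = self.W_h(x.V)                       # (L, h, 3)
            s_in = concat([Vh.norm(axis=-1), x.s], axis=-1)
        else:
            s_in = x.s
        s_out = self.W_m(s_in)
        if self.activations:
            s_out = s_out.relu()
        if vo > 0:
            Vmu = self.W_mu(Vh)                       # (L, vo, 3)
            gate = Vmu.norm(axis=-1, keepdims=True)   # (L, vo, 1)
            if self.activations or self.vector_gate:
                V_out = Vmu * gate.sigmoid()
            else:
                V_out = Vmu
        else:
            L = x.s.shape[0]
            V_out = Tensor(np.zeros((L, 0, 3)))
        return ScalarVector(s_out, V_out)


class SVLayerNorm(Module):
    """LayerNorm split over the scalar/vector halves.

    Scalars are standardized over the channel axis with a learned affine;
    vector channels are jointly rescaled by the root-mean-square of their
    norms (no recentering — subtracting a mean vector would break
    equivariance only under translation of features, but rescaling by an
    invariant is the only safe normalization for directions).
    """

    def __init__(self, dims: tuple, eps: float = 1e-8):
        ns, nv = dims
        self.nv = nv
        self.eps = eps
        self.gamma = Tensor(np.ones(ns), requires_grad=True)
        self.beta = Tensor(np.zeros(ns), requires_grad=True)

    def __call__(self, x: ScalarVector) -> ScalarVector:
        s = x.s
        mu = s.mean(axis=-1, keepdims=True)
        var = ((s - mu) ** 2).mean(axis=-1, keepdims=True)
        s_out = (s - mu) / (var + self.eps).sqrt() * self.gamma + self.beta
        if self.nv > 0:
            sq = (x.V**2).sum(axis=-1).mean(axis=-1, keepdims=True)  # (L, 1)
            rms = (sq + self.eps).sqrt()
            V_out = x.V / rms.reshape(rms.shape[0], 1, 1)
        else:
            V_out = x.V
        return ScalarVector(s_out, V_out)


@dataclass
class GnnConfig:
    """Architecture hyperparameters for the message-passing trunk.

    The defaults (64 scalar / 8 vector node channels, 3 layers, 3-GVP
    message stacks, dropout 0.1) balance expressiveness against CPU-only
    training cost; every width is configurable.
    """

    node_dims: tuple = (64, 8)
    edge_dims: tuple = (32, 1)
    n_layers: int = 3
    msg_depth: int = 3
    dropout: float = 0.1
    out_scalar_dim: int = 64
    aggregation: str = "mean"            # "mean" (neighbor count) or "width"
    message_source: str = "source"       # "source" (h_v^j) or "dest" (literal h_v^i)

    def __post_init__(self):
        if self.n_layers < 1 or self.msg_depth < 1:
            raise ValueError("need at least one layer and one message GVP")
        if any(w <= 0 for w in (*self.node_dims, *self.edge_dims, self.out_scalar_dim)):
            raise ValueError("all widths must be positive")
        if self.aggregation not in ("mean", "width"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.message_source not in ("source", "dest"):
            raise ValueError(f"unknown message_source {self.message_source!r}")


class GVPConv(Module):
    """One message-passing layer: GVP message stack + residual mean update."""

    def __init__(self, cfg: GnnConfig, rng: np.random.Generator):
        ns, nv = cfg.node_dims
        es, ev = cfg.edge_dims
        in_dims = (ns + es, nv + ev)
        stack = []
        for i in range(cfg.msg_depth):
            last = i == cfg.msg_depth - 1
            stack.append(GVP(in_dims if i == 0 else cfg.node_dims, cfg.node_dims,
                             rng, activations=not last, vector_gate=True))
        self.stack = stack
        self.cfg = cfg
        self.norm = SVLayerNorm(cfg.node_dims)
        self.drop_s = Dropout(cfg.dropout)
        self.drop_v = Dropout(cfg.dropout)

    def message(self, h_v: ScalarVector, h_e: ScalarVector,
                edge_index: np.ndarray) -> ScalarVector:
        src, dst = edge_index
        node_side = src if self.cfg.message_source == "source" else dst
        m = h_v.gather(node_side).cat(h_e)
        for gvp in self.stack:
            m = gvp(m)
        return m

    def __call__(self, h_v: ScalarVector, h_e: ScalarVector,
                 edge_index: np.ndarray, rng: np.random.Generator) -> ScalarVector:
        L = h_v.s.shape[0]
        msg = self.message(h_v, h_e, edge_index)
        dst = edge_index[1]
        if self.cfg.aggregation == "mean":
            counts = np.bincount(dst, minlength=L).astype(np.float64)
            denom = np.maximum(counts, 1.0)
        else:
            denom = np.full(L, float(sum(self.cfg.node_dims)))
        agg_s = msg.s.segment_sum(dst, L) / Tensor(denom[:, None])
        agg_V = msg.V.segment_sum(dst, L) / Tensor(denom[:, None, None])
        agg = ScalarVector(self.drop_s(agg_s, rng), self.drop_v(agg_V, rng))
        return self.norm(h_v + agg)


class GVPBackbone(Module):
    """Input lifting GVPs, stacked GVPConv layers, and the scalar collapse.

    `forward` returns the L x D rotation-invariant feature map F: per-node
    hidden states after message passing, folded to scalars by a final GVP
    with vector output width 0.
    """

    def __init__(self, in_node_dims: tuple, in_edge_dims: tuple,
                 cfg: GnnConfig, rng: np.random.Generator):
        self.cfg = cfg
        # separate lifting GVPs for node and edge features
        self.node_in = GVP(in_node_dims, cfg.node_dims, rng, activations=False)
        self.edge_in = GVP(in_edge_dims, cfg.edge_dims, rng, activations=False)
        self.layers = [GVPConv(cfg, rng) for _ in range(cfg.n_layers)]
        self.collapse = GVP(cfg.node_dims, (cfg.out_scalar_dim, 0), rng,
                            activations=False)

    def lift(self, node: ScalarVector, edge: ScalarVector) -> tuple:
        return self.node_in(node), self.edge_in(edge)

    def propagate(self, h_v: ScalarVector, h_e: ScalarVector,
                  edge_index: np.ndarray, rng: np.random.Generator) -> ScalarVector:
        for layer in self.layers:
            h_v = layer(h_v, h_e, edge_index, rng)
        return h_v

    def collapse_to_scalars(self, h_v: ScalarVector) -> Tensor:
        return self.collapse(h_v).s

    def forward(self, node: ScalarVector, edge: ScalarVector,
                edge_index: np.ndarray, rng: np.random.Generator) -> Tensor:
        h_v, h_e = self.lift(node, edge)
        h_v = self.propagate(h_v, h_e, edge_index, rng)
        return self.collapse_to_scalars(h_v)
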