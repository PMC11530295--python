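"""Two-stage supernode graph-attention pooling and the prediction head.

Stage 1: a set of n trainable supernode queries attends over the residues
of each graph.  Keys and values come from two independent one-pass graph
convolutions over the residue graph; multi-head attention rows (softmax
over residues) are concatenated and mapped per-supernode by an MLP into the
important-node matrix A (n x d per protein).

Stage 2: a single trainable query pools the supernodes,
z = softmax(Q_p (A K_p)^T / sqrt(d)) A V_p, giving one d-vector per
protein, which an MLP plus elementwise sigmoid turns into per-term scores.

Everything is invariant to residue relabeling (the queries are
node-independent) and operates on batches of graphs padded to a common
length with masked softmax.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import Module, Linear, MLP

_NEG = -1e9  # additive mask for padded positions


def gcn_coefficients(edge_index: np.ndarray, n_nodes: int):
    """Symmetric GCN normalization with self-loops.

    Degrees count incoming edges plus the self-loop; edge j->i gets weight
    1/sqrt(d_i d_j).  Returns (src, dst, coeff) including the self-loops.
    """
    src, dst = edge_index
    deg = np.bincount(dst, minlength=n_nodes).astype(np.float64) + 1.0
    loops = np.arange(n_nodes)
    all_src = np.concatenate([src, loops])
    all_dst = np.concatenate([dst, loops])
    coeff = 1.0 / np.sqrt(deg[all_src] * deg[all_dst])
    return all_src, all_dst, coeff


class GraphEncoder(Module):
    """One graph-convolution pass: normalized aggregation, linear, ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin = Linear(d_in, d_out, rng)

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        n = x.shape[0]
        src, dst, coeff = gcn_coefficients(edge_index, n)
        msg = x.gather(src) * Tensor(coeff[:, None])
        agg = msg.segment_sum(dst, n)
        return self.lin(agg).relu()


def _pad_rows(x: Tensor, graph_sizes: np.ndarray):
    """Reshape flat per-node rows into (B, Lmax, d) with a padding mask.

    Padding rows point at an appended zero row, so gradients flow only to
    real nodes.
    """
    B = len(graph_sizes)
    Lmax = int(graph_sizes.max())
    N = int(graph_sizes.sum())
    index = np.full((B, Lmax), N, dtype=np.int64)
    off = 0
    for b, size in enumerate(graph_sizes):
        index[b, :size] = np.arange(off, off + size)
        off += size
    zero_row = Tensor(np.zeros((1, x.shape[1])))
    padded = concat([x, zero_row], axis=0).gather(index.ravel())
    padded = padded.reshape(B, Lmax, x.shape[1])
    mask = index < N                                  # (B, Lmax) bool
    return padded, mask


class GapHead(Module):
    """Supernode attention pooling + sigmoid multi-label readout.

    Parameters: d feature width (divisible by the head count), n supernodes,
    H heads, C output terms.  The supernode query matrix is initialized from
    a seeded normal with std 1/sqrt(d).
    """

    def __init__(self, d: int, n_classes: int, rng: np.random.Generator,
                 n_super: int = 64, n_heads: int = 4):
        if n_super < 1:
            raise ValueError("need at least one supernode")
        if d % n_heads != 0:
            raise ValueError(f"feature width {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_super = n_super
        self.n_heads = n_heads
        self.n_classes = n_classes
        self.Q = Tensor(rng.standard_normal((n_super, d)) / np.sqrt(d),
                        requires_grad=True)
        self.enc_k = GraphEncoder(d, d, rng)
        self.enc_v = GraphEncoder(d, d, rng)
        self.merge = MLP(d, d, d, rng)
        self.Qp = Tensor(rng.standard_normal((1, d)) / np.sqrt(d), requires_grad=True)
        self.Kp = Tensor(rng.standard_normal((d, d)) / np.sqrt(d), requires_grad=True)
        self.Vp = Tensor(rng.standard_normal((d, d)) / np.sqrt(d), requires_grad=True)
        self.out = MLP(d, d, n_classes, rng)

    # ---------------------------------------------------------------- stages
    def graph_encode(self, node_scalars: Tensor, edge_index: np.ndarray):
        """Keys and values from the two independent graph encoders."""
        return (self.enc_k(node_scalars, edge_index),
                self.enc_v(node_scalars, edge_index))

    def supernode_attention(self, node_scalars: Tensor, edge_index: np.ndarray,
                            graph_sizes: np.ndarray) -> Tensor:
        """Important-node matrices A, shape (B, n_super, d)."""
        if node_scalars.shape[0] == 0:
            raise ValueError("empty graph batch")
        K, V = self.graph_encode(node_scalars, edge_index)
        Kp_, mask = _pad_rows(K, graph_sizes)          # (B, Lmax, d)
        Vp_, _ = _pad_rows(V, graph_sizes)
        B, Lmax, d = Kp_.shape
        dh = d // self.n_heads
        bias = Tensor(np.where(mask, 0.0, _NEG)[:, None, :])   # (B, 1, Lmax)
        heads = []
        for h in range(self.n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            Qh = self.Q[:, sl]                                  # (n, dh)
            Kh = Kp_[:, :, sl]                                  # (B, Lmax, dh)
            Vh = Vp_[:, :, sl]
            scores = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dh)   # (B, n, Lmax)
            attn = (scores + bias).softmax(axis=-1)
            heads.append(attn @ Vh)                             # (B, n, dh)
        gamma = concat(heads, axis=-1)                          # (B, n, d)
        return self.merge(gamma)

    def global_pool(self, A: Tensor) -> Tensor:
        """Second-stage pooling: (B, n, d) -> (B, d)."""
        AK = A @ self.Kp                                        # (B, n, d)
        scores = self.Qp @ AK.transpose(0, 2, 1) / np.sqrt(self.d)  # (B, 1, n)
        attn = scores.softmax(axis=-1)
        z = attn @ (A @ self.Vp)                                # (B, 1, d)
        return z.reshape(z.shape[0], self.d)

    def logits(self, z: Tensor) -> Tensor:
        return self.out(z)

    def predict_head(self, z: Tensor) -> Tensor:
        """Per-term probabilities in (0, 1)."""
        return self.logits(z).sigmoid()

    def __call__(self, node_scalars: Tensor, edge_index: np.ndarray,
                 graph_sizes: np.ndarray):
        """Full head: returns (z, logits) for a flat node batch."""
        A = self.supernode_attention(node_scalars, edge_index, graph_sizes)
        z = self.global_pool(A)
        return z, self.logits(z)
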