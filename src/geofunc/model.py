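"""Full predictor: equivariant trunk + attention pooling + sigmoid readout.

Graphs are batched block-diagonally (edge indices offset, node features
concatenated); the pooling head receives per-graph sizes so attention never
crosses protein boundaries.  The model is a pure function of its parameters
and the input graph — evaluation mode has no stochastic elements, so
repeated forwards are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .nn import Module
from .features import ResidueGraph, FeatureManifest
from .gvp import ScalarVector, GVPBackbone, GnnConfig
from .gap import GapHead

__all__ = ["ModelConfig", "FunctionPredictor", "GraphBatch", "batch_graphs"]


@dataclass
class GraphBatch:
    """Block-diagonal composition of several residue graphs."""

    node: ScalarVector
    edge: ScalarVector
    edge_index: np.ndarray
    graph_sizes: np.ndarray
    names: list


def batch_graphs(graphs: list) -> GraphBatch:
    if not graphs:
        raise ValueError("empty graph list")
    ns = np.concatenate([g.node_scalar for g in graphs])
    nv = np.concatenate([g.node_vector for g in graphs])
    es = np.concatenate([g.edge_scalar for g in graphs])
    ev = np.concatenate([g.edge_vector for g in graphs])
    sizes = np.array([g.n_nodes for g in graphs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    edge_index = np.concatenate(
        [g.edge_index + off for g, off in zip(graphs, offsets)], axis=1)
    return GraphBatch(node=ScalarVector.from_arrays(ns, nv),
                      edge=ScalarVector.from_arrays(es, ev),
                      edge_index=edge_index, graph_sizes=sizes,
                      names=[g.name for g in graphs])


@dataclass
class ModelConfig:
    """Widths and counts for the whole network; all serializable."""

    n_classes: int = 2
    node_in_dims: tuple = (40, 3)     # from the feature manifest
    edge_in_dims: tuple = (32, 1)
    gnn: GnnConfig = field(default_factory=GnnConfig)
    n_super: int = 64
    n_heads: int = 4
    seed: int = 0

    @classmethod
    def for_manifest(cls, manifest: FeatureManifest, n_classes: int,
                     **kwargs) -> "ModelConfig":
        return cls(n_classes=n_classes,
                   node_in_dims=(manifest.node_scalar_dim, manifest.node_vector_dim),
                   edge_in_dims=(manifest.edge_scalar_dim, manifest.edge_vector_dim),
                   **kwargs)

    def to_json(self) -> str:
        d = asdict(self)
        d["node_in_dims"] = list(self.node_in_dims)
        d["edge_in_dims"] = list(self.edge_in_dims)
        for key in ("node_dims", "edge_dims"):
            d["gnn"][key] = list(d["gnn"][key])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        gnn = d.pop("gnn")
        gnn["node_dims"] = tuple(gnn["node_dims"])
        gnn["edge_dims"] = tuple(gnn["edge_dims"])
        d["node_in_dims"] = tuple(d["node_in_dims"])
        d["edge_in_dims"] = tuple(d["edge_in_dims"])
        return cls(gnn=GnnConfig(**gnn), **d)


def perturb_scalar_vector(h: ScalarVector, eps_max: float,
                          rng: np.random.Generator) -> ScalarVector:
    """Sign-preserving bounded noise h' = h + |eps| sign(h), eps ~ U(0, eps_max).

    Applied to scalar and vector channels alike; zero entries stay zero
    (sign(0) = 0), so undefined-geometry sentinels are untouched.
    """
    if eps_max < 0:
        raise ValueError("eps_max must be nonnegative")

    def one(t: Tensor) -> Tensor:
        eps = rng.uniform(0.0, eps_max, size=t.shape)
        return t + Tensor(np.abs(eps) * np.sign(t.data))

    return ScalarVector(one(h.s), one(h.V))


class FunctionPredictor(Module):
    """End-to-end model mapping a graph batch to per-term scores."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = GVPBackbone(cfg.node_in_dims, cfg.edge_in_dims, cfg.gnn, rng)
        self.head = GapHead(cfg.gnn.out_scalar_dim, cfg.n_classes, rng,
                            n_super=cfg.n_super, n_heads=cfg.n_heads)
        self.training = False

    def forward(self, batch: GraphBatch, rng: np.random.Generator | None = None,
                perturb_eps: float | None = None) -> dict:
        """Run the model; returns dict with F, z, logits, scores (Tensors).

        `perturb_eps`, if given, applies the contrastive sign-preserving
        noise to the lifted node features (after the initial GVP embedding).
        Dropout requires `rng` and is active only in training mode.
        """
        if rng is None:
            rng = np.random.default_rng(0)
        h_v, h_e = self.backbone.lift(batch.node, batch.edge)
        if perturb_eps is not None:
            h_v = perturb_scalar_vector(h_v, perturb_eps, rng)
        h_v = self.backbone.propagate(h_v, h_e, batch.edge_index, rng)
        F = self.backbone.collapse_to_scalars(h_v)
        z, logits = self.head(F, batch.edge_index, batch.graph_sizes)
        return {"F": F, "z": z, "logits": logits, "scores": logits.sigmoid()}

    def predict(self, graphs: list) -> np.ndarray:
        """Deterministic eval-mode scores, shape (len(graphs), C)."""
        self.set_training(False)
        out = self.forward(batch_graphs(graphs))
        return out["scores"].data.copy()

    # ------------------------------------------------------------ checkpoint
    def save(self, path):
        path = Path(path)
        state = self.state_dict()
        np.savez(path.with_suffix(".npz"), **state)
        path.with_suffix(".json").write_text(self.cfg.to_json())

    @classmethod
    def load(cls, path) -> "FunctionPredictor":
        path = Path(path)
        cfg = ModelConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
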