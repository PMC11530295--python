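"""Residue-level attribution with gradient-weighted class activation maps.

For one protein and one GO term, the feature map F (L x D, the
rotation-invariant per-residue output of the trunk) is weighted by the
gradient of the term's pre-sigmoid logit with respect to each entry:

    W_ij = d y_l / d F_ij,     CAM_i = ReLU( sum_j W_ij F_ij / D )

The per-element weighting follows the definition exactly (no spatial
averaging of gradients, unlike image-style CAM); the logit rather than the
sigmoid output is differentiated so attribution does not vanish at
saturated predictions.  Scores inherit the trunk's rotation invariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve, auc as _auc

from .model import FunctionPredictor, batch_graphs
from .features import ResidueGraph
from .structure import BackboneStructure, write_backbone_pdb

__all__ = ["CamScores", "grad_cam", "cam_to_structure", "residue_roc"]


@dataclass
class CamScores:
    """Nonnegative per-residue contribution scores for one protein/term."""

    scores: np.ndarray
    protein_id: str
    term_index: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any(self.scores < 0):
            raise ValueError("CAM scores must be nonnegative")

    def __len__(self):
        return len(self.scores)

    def normalized(self) -> np.ndarray:
        """Min-max to [0, 1]; a constant map normalizes to all zeros."""
        lo, hi = self.scores.min(), self.scores.max()
        if hi - lo < 1e-30:
            return np.zeros_like(self.scores)
        return (self.scores - lo) / (hi - lo)


def grad_cam(model: FunctionPredictor, graph: ResidueGraph,
             term_index: int) -> CamScores:
    """Grad-CAM residue scores for `term_index` on a single graph."""
    if not 0 <= term_index < model.cfg.n_classes:
        raise IndexError(f"term index {term_index} out of range "
                         f"[0, {model.cfg.n_classes})")
    model.set_training(False)
    out = model.forward(batch_graphs([graph]))
    F = out["F"]                                   # (L, D)
    y_l = out["logits"][0, term_index]             # pre-sigmoid scalar
    y_l.backward()
    W = F.grad                                     # (L, D)
    D = F.shape[1]
    cam = np.maximum((W * F.data).sum(axis=1) / D, 0.0)
    return CamScores(scores=cam, protein_id=graph.name, term_index=term_index)


def cam_to_structure(s: BackboneStructure, cam: CamScores, path) -> None:
    """Write the structure with normalized CAM in the B-factor column.

    Also writes `<path>.tsv` with residue index, amino acid, and the raw
    score to six decimals.
    """
    if len(s) != len(cam):
        raise ValueError(f"structure length {len(s)} != CAM length {len(cam)}")
    path = Path(path)
    write_backbone_pdb(s, path, bfactors=cam.normalized())
    lines = ["residue\taa\tscore"]
    for i in range(len(s)):
        lines.append(f"{s.seq_pos[i]}\t{s.aa[i]}\t{cam.scores[i]:.6f}")
    path.with_suffix(path.suffix + ".tsv").write_text("\n".join(lines) + "\n")


def residue_roc(cam: CamScores, truth: np.ndarray) -> tuple:
    """ROC curve and AUC of the CAM scores against binary residue labels.

    Returns ((fpr, tpr, thresholds), auc); both classes must be present.
    """
    truth = np.asarray(truth).astype(int)
    if truth.shape != cam.scores.shape:
        raise ValueError("truth length must match CAM length")
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    fpr, tpr, thr = roc_curve(truth, cam.scores)
    return (fpr, tpr, thr), float(_auc(fpr, tpr))
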