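"""GO-aware labels and protein-centric CAFA evaluation.

Annotations live in an `AnnotationSet`: a binary protein x term matrix, the
GO DAG (child -> parents), per-term namespaces, and per-term information
content.  Labels are closed under the true-path rule before any metric is
computed.  Metrics follow the CAFA protocol: Fmax (protein-centric maximum
F1 over a 0.01-step threshold sweep), micro-averaged AUPR over all
protein-term pairs, and Smin (minimum semantic distance with IC-weighted
remaining uncertainty and misinformation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

__all__ = ["AnnotationSet", "propagate_labels", "information_content",
           "fmax", "aupr", "smin", "load_dag_edges", "load_obo",
           "load_annotations", "evaluate_by_namespace", "THRESHOLDS"]

THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


# --------------------------------------------------------------------------
# DAG handling
# --------------------------------------------------------------------------

def _ancestor_matrix(terms: list, dag: dict) -> np.ndarray:
    """Boolean (T, T) matrix: anc[i, j] True if term j is an ancestor of i
    (including i itself)."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parents in dag.items():
        for p in parents:
            if child in g and p in g:
                g.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("GO DAG contains a cycle")
    idx = {t: i for i, t in enumerate(terms)}
    anc = np.eye(len(terms), dtype=bool)
    for t in terms:
        for a in nx.descendants(g, t):      # edges point child -> parent
            anc[idx[t], idx[a]] = True
    return anc


def propagate_labels(dag: dict, labels: np.ndarray, terms: list) -> np.ndarray:
    """Close a binary label matrix under the true-path rule.

    Every protein annotated with a term becomes annotated with all its
    ancestors.  Idempotent; raises on a cyclic DAG.
    """
    labels = np.asarray(labels, dtype=bool)
    anc = _ancestor_matrix(terms, dag)
    return (labels @ anc).astype(np.int8)


def information_content(train_labels: np.ndarray) -> np.ndarray:
    """Per-term IC in bits: -log2(n_t / N) over the closed training labels.

    Terms never seen in training get +inf (excluded from Smin downstream).
    """
    train_labels = np.asarray(train_labels)
    N = train_labels.shape[0]
    if N == 0:
        raise ValueError("empty training set")
    n_t = train_labels.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore"):
        ic = -np.log2(n_t / N)
    return ic


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def fmax(y_true: np.ndarray, y_score: np.ndarray) -> tuple:
    """Protein-centric Fmax over the CAFA threshold grid.

    At each threshold, precision is averaged over proteins with at least
    one prediction at or above the threshold and recall over proteins with
    at least one true term; returns (Fmax, best threshold), ties resolved
    toward the smallest threshold.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=np.float64)
    if y_true.shape != y_score.shape:
        raise ValueError("shape mismatch")
    has_true = y_true.any(axis=1)
    if not has_true.any():
        raise ValueError("no protein has a true term")
    best_f, best_t = 0.0, float(THRESHOLDS[0])
    n_true = y_true.sum(axis=1).astype(np.float64)
    for t in THRESHOLDS:
        pred = y_score >= t
        n_pred = pred.sum(axis=1).astype(np.float64)
        tp = (pred & y_true).sum(axis=1).astype(np.float64)
        covered = n_pred > 0
        if not covered.any():
            continue
        pr = float(np.mean(tp[covered] / n_pred[covered]))
        rc = float(np.mean(tp[has_true] / n_true[has_true]))
        if pr + rc == 0:
            continue
        f = 2 * pr * rc / (pr + rc)
        if f > best_f + 1e-15:
            best_f, best_t = f, float(t)
    return best_f, best_t


def aupr(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Micro-averaged area under the precision-recall curve.

    All protein-term pairs are pooled and ranked; the area uses step-wise
    interpolation, summing precision at each recall increment (ties in the
    scores are grouped so tied pairs enter together).
    """
    y = np.asarray(y_true).ravel().astype(bool)
    s = np.asarray(y_score, dtype=np.float64).ravel()
    P = y.sum()
    if P == 0:
        raise ValueError("no positive protein-term pair")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, len(y) + 1)
    # keep only the last index of each tied-score block
    block_end = np.nonzero(np.diff(s_sorted, append=np.nan) != 0)[0]
    tp_b = tp[block_end].astype(np.float64)
    n_b = n_pred[block_end].astype(np.float64)
    precision = tp_b / n_b
    recall = tp_b / P
    d_recall = np.diff(recall, prepend=0.0)
    return float(np.sum(precision * d_recall))


def smin(y_true: np.ndarray, y_score: np.ndarray, ic: np.ndarray) -> tuple:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid.

    ru(t) is the mean per-protein IC mass of false negatives, mi(t) of
    false positives.  Every scored term must have finite IC.  Returns
    (Smin, best threshold).
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=np.float64)
    ic = np.asarray(ic, dtype=np.float64)
    if not np.all(np.isfinite(ic)):
        raise ValueError("non-finite IC for a scored term; filter such terms first")
    best_s, best_t = np.inf, float(THRESHOLDS[0])
    for t in THRESHOLDS:
        pred = y_score >= t
        fn = y_true & ~pred
        fp = pred & ~y_true
        ru = float(np.mean(fn @ ic))
        mi = float(np.mean(fp @ ic))
        val = float(np.sqrt(ru**2 + mi**2))
        if val < best_s - 1e-15:
            best_s, best_t = val, float(t)
    return best_s, best_t


# --------------------------------------------------------------------------
# annotation container and IO
# --------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Proteins x GO terms with DAG, namespaces, and information content."""

    proteins: list
    terms: list
    dag: dict = field(default_factory=dict)       # child -> list of parents
    namespaces: dict = field(default_factory=dict)  # term -> MF/BP/CC
    labels: np.ndarray = None                     # (P, T) int8, closed
    ic: np.ndarray = None

    def __post_init__(self):
        if self.labels is None:
            self.labels = np.zeros((len(self.proteins), len(self.terms)), dtype=np.int8)
        self.labels = propagate_labels(self.dag, self.labels, self.terms)

    def compute_ic(self, train_labels: np.ndarray | None = None):
        self.ic = information_content(
            self.labels if train_labels is None else train_labels)
        return self.ic

    def namespace_mask(self, ns: str) -> np.ndarray:
        return np.array([self.namespaces.get(t, "MF") == ns for t in self.terms])


def load_dag_edges(path) -> dict:
    """Two-column child/parent TSV -> child -> parents dict."""
    dag: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        child, parent = line.split("\t")[:2]
        dag.setdefault(child, []).append(parent)
    return dag


def load_obo(path) -> tuple:
    """GO DAG from an OBO file via obonet (is_a and part_of edges).

    Returns (dag, namespaces).
    """
    import obonet

    g = obonet.read_obo(str(path))
    dag: dict = {}
    namespaces: dict = {}
    ns_map = {"molecular_function": "MF", "biological_process": "BP",
              "cellular_component": "CC"}
    for node, data in g.nodes(data=True):
        namespaces[node] = ns_map.get(data.get("namespace", ""), "MF")
        parents = list(g.successors(node))   # obonet: child -> parent edges
        if parents:
            dag[node] = parents
    return dag, namespaces


def load_annotations(path, dag: dict | None = None,
                     namespaces: dict | None = None) -> AnnotationSet:
    """Protein/GO-term two-column TSV -> AnnotationSet (labels closed)."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        prot, term = line.split("\t")[:2]
        pairs.append((prot, term))
    proteins = sorted({p for p, _ in pairs})
    dag = dag or {}
    terms = sorted({t for _, t in pairs} | {p for ps in dag.values() for p in ps}
                   | set(dag.keys()))
    pi = {p: i for i, p in enumerate(proteins)}
    ti = {t: i for i, t in enumerate(terms)}
    labels = np.zeros((len(proteins), len(terms)), dtype=np.int8)
    for p, t in pairs:
        labels[pi[p], ti[t]] = 1
    return AnnotationSet(proteins=proteins, terms=terms, dag=dag,
                         namespaces=namespaces or {}, labels=labels)


def evaluate_by_namespace(ann: AnnotationSet, y_score: np.ndarray,
                          ic: np.ndarray | None = None) -> dict:
    """Fmax/AUPR/Smin per GO namespace present in the annotation set.

    Smin is reported only where every namespace term has finite IC.
    AUPR is micro-averaged over protein-term pairs within the namespace.
    """
    ic = ic if ic is not None else (ann.ic if ann.ic is not None else ann.compute_ic())
    out = {}
    for ns in ("MF", "BP", "CC"):
        mask = ann.namespace_mask(ns)
        if not mask.any():
            continue
        yt = ann.labels[:, mask]
        ys = y_score[:, mask]
        if not yt.any():
            continue
        entry = {"n_terms": int(mask.sum())}
        entry["fmax"], entry["fmax_threshold"] = fmax(yt, ys)
        entry["aupr"] = aupr(yt, ys)
        ns_ic = ic[mask]
        if np.all(np.isfinite(ns_ic)):
            entry["smin"], entry["smin_threshold"] = smin(yt, ys, ns_ic)
        out[ns] = entry
    return out
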