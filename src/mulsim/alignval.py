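"""Alignment use-case and evaluation on top of a similarity matrix.

A node mapping is built per layer, either as a maximum-weight bipartite
matching (the default, via the Hungarian algorithm) or greedily by
repeatedly taking the largest remaining similarity.  Node Correctness
(NC) is the fraction of mapped source nodes whose image equals the known
true counterpart.  The binary-classification view labels a same-layer
pair positive iff it is a true counterpart pair and predicts positive iff
its similarity clears a threshold (default 0.95), from which the standard
KPIs (accuracy, AUC, sensitivity, specificity, precision, F1) follow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_auc_score

from .netio import NodeRef
from .simscore import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMapping",
    "KPIReport",
    "align",
    "node_correctness",
    "classify",
    "kpis",
]


@dataclass
class NodeMapping:
    """Injective partial map from source nodes to same-layer target nodes."""

    pairs: dict[NodeRef, NodeRef]

    def __post_init__(self) -> None:
        images = list(self.pairs.values())
        if len(set(images)) != len(images):
            raise ValueError("mapping is not injective")

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, node: NodeRef) -> NodeRef:
        return self.pairs[node]

    def get(self, node: NodeRef, default=None):
        return self.pairs.get(node, default)

    def total_similarity(self, matrix: SimilarityMatrix) -> float:
        total = 0.0
        for block in matrix.blocks:
            spos = {n: i for i, n in enumerate(block.source_order)}
            tpos = {n: j for j, n in enumerate(block.target_order)}
            for s, t in self.pairs.items():
                if s in spos and t in tpos:
                    total += float(block.values[spos[s], tpos[t]])
        return total


def _lexical_block(block) -> tuple[list[int], list[int], np.ndarray]:
    """Row/column orders sorted by node name so ties break lexically."""
    ridx = sorted(range(len(block.source_order)), key=lambda i: block.source_order[i])
    cidx = sorted(range(len(block.target_order)), key=lambda j: block.target_order[j])
    return ridx, cidx, block.values[np.ix_(ridx, cidx)]


def align(matrix: SimilarityMatrix, method: str = "matching") -> NodeMapping:
    """Per-layer one-to-one node mapping from similarities.

    ``matching`` maximizes the total similarity of the mapping (Hungarian
    algorithm); ``greedy`` repeatedly takes the largest remaining entry.
    Ties break deterministically by (source name, target name).
    """
    if method not in ("matching", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    pairs: dict[NodeRef, NodeRef] = {}
    for block in matrix.blocks:
        if block.values.size == 0:
            continue
        ridx, cidx, vals = _lexical_block(block)
        if method == "matching":
            rows, cols = linear_sum_assignment(vals, maximize=True)
            for r, c in zip(rows, cols):
                pairs[block.source_order[ridx[r]]] = block.target_order[cidx[c]]
        else:
            order = np.argsort(-vals, axis=None, kind="stable")
            used_r: set[int] = set()
            used_c: set[int] = set()
            for flat in order:
                r, c = divmod(int(flat), vals.shape[1])
                if r in used_r or c in used_c:
                    continue
                used_r.add(r)
                used_c.add(c)
                pairs[block.source_order[ridx[r]]] = block.target_order[cidx[c]]
                if len(used_r) == min(vals.shape):
                    break
    return NodeMapping(pairs=pairs)


def node_correctness(mapping: NodeMapping, truth: NodeMapping) -> float:
    """Fraction of true pairs the mapping reproduces, over |domain(truth)|."""
    if not truth.pairs:
        raise ValueError("ground-truth mapping is empty")
    hits = sum(1 for s, t in truth.pairs.items() if mapping.get(s) == t)
    return hits / len(truth.pairs)


def classify(
    matrix: SimilarityMatrix,
    truth: NodeMapping,
    threshold: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary-classification view over all same-layer pairs.

    Returns ``(labels, predictions, scores)``: label 1 iff the pair is a
    true counterpart pair, prediction 1 iff similarity >= threshold,
    scores are the raw similarities (for AUC).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    labels: list[int] = []
    preds: list[int] = []
    scores: list[float] = []
    for block in matrix.blocks:
        for i, s in enumerate(block.source_order):
            true_t = truth.get(s)
            for j, t in enumerate(block.target_order):
                sim = float(block.values[i, j])
                labels.append(1 if true_t == t else 0)
                preds.append(1 if sim >= threshold else 0)
                scores.append(sim)
    return np.asarray(labels), np.asarray(preds), np.asarray(scores)


@dataclass
class KPIReport:
    accuracy: float
    auc: float | None
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def kpis(labels, predictions, scores) -> KPIReport:
    """Confusion-matrix KPIs plus rank-statistic AUC (tie-corrected).

    Zero-denominator ratios are reported as 0 with a warning; if labels
    are all-positive or all-negative, AUC is omitted (None) with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(labels) == len(predictions) == len(scores)):
        raise ValueError("labels, predictions and scores must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    n = tp + fp + tn + fn

    accuracy = _safe_ratio(tp + tn, n, "accuracy")
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    precision = _safe_ratio(tp, tp + fp, "precision")
    f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity, "f1")

    if len(set(labels.tolist())) < 2:
        warnings.warn("degenerate label set; AUC omitted", stacklevel=2)
        auc: float | None = None
    else:
        auc = float(roc_auc_score(labels, scores))

    return KPIReport(
        accuracy=accuracy,
        auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
    )


def write_mapping(mapping: NodeMapping, stream) -> int:
    """TSV export: source, target, layer."""
    stream.write("source\ttarget\tlayer\n")
    count = 0
    for s, t in sorted(mapping.pairs.items()):
        stream.write(f"{s.name}\t{t.name}\t{s.layer}\n")
        count += 1
    return count
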