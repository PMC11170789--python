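"""Jaccard-type similarity between node embeddings, layer-on-layer.

The classical Jaccard coefficient Jc(A, B) = |A ∩ B| / |A ∪ B| is defined
on sets; node embeddings are real vectors, so we use its weighted
(Ruzicka) generalization Σ_i min(a_i, b_i) / Σ_i max(a_i, b_i), computed
after rectifying negative components to zero.  On binary vectors this
reduces exactly to the set form, and the score is always in [0, 1].

Scoring is strictly layer-on-layer: heterogeneous entities (a gene layer
versus a disease layer) are never compared, so the similarity matrix is a
list of per-layer blocks with no cross-layer entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import NodeRef

__all__ = [
    "LayerBlock",
    "SimilarityMatrix",
    "jaccard_sets",
    "jaccard_weighted",
    "signed_split",
    "similarity_matrix",
    "similarity_from_batches",
]


def jaccard_sets(A: set, B: set) -> float:
    """Intersection-over-union; two empty sets count as identical (1.0)."""
    if not A and not B:
        return 1.0
    return len(A & B) / len(A | B)


def jaccard_weighted(a: np.ndarray, b: np.ndarray, *, empty_value: float = 1.0) -> float:
    """Weighted (Ruzicka) Jaccard on real vectors, negatives rectified to 0.

    Both vectors all-zero after rectification -> ``empty_value`` (default
    1.0: structurally identical isolated nodes); exactly one all-zero -> 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in input vectors")
    a = np.maximum(a, 0.0)
    b = np.maximum(b, 0.0)
    denom = np.maximum(a, b).sum()
    if denom == 0.0:
        return empty_value
    return float(np.minimum(a, b).sum() / denom)


@dataclass
class LayerBlock:
    """All pairwise similarities for one layer position."""

    layer: str
    source_order: list[NodeRef]
    target_order: list[NodeRef]
    values: np.ndarray  # |source| x |target|, entries in [0, 1]


@dataclass
class SimilarityMatrix:
    """Layer-blocked source x target similarities; no cross-layer entries."""

    blocks: list[LayerBlock]

    @property
    def n_entries(self) -> int:
        return sum(b.values.size for b in self.blocks)

    def block_for(self, layer: str) -> LayerBlock:
        for b in self.blocks:
            if b.layer == layer:
                return b
        raise KeyError(layer)


def signed_split(X: np.ndarray) -> np.ndarray:
    """Embed real vectors into the non-negative cone as ``[x+, (-x)+]``.

    The weighted Jaccard is defined on non-negative vectors; simply
    clipping negatives discards half of a zero-centred embedding.  The
    signed decomposition keeps the full signal, is the identity (up to
    zero padding) on already non-negative input, and preserves the
    reduction of the weighted form to the set form on binary vectors.
    """
    X = np.asarray(X, dtype=np.float64)
    return np.hstack([np.maximum(X, 0.0), np.maximum(-X, 0.0)])


def _rectified_block(
    X1: np.ndarray, X2: np.ndarray, empty_value: float
) -> np.ndarray:
    """Vectorized Ruzicka similarity between all row pairs of X1 and X2."""
    A = np.maximum(X1, 0.0)[:, None, :]  # n1 x 1 x d
    B = np.maximum(X2, 0.0)[None, :, :]  # 1 x n2 x d
    num = np.minimum(A, B).sum(axis=2)
    den = np.maximum(A, B).sum(axis=2)
    out = np.full(num.shape, empty_value, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def similarity_matrix(
    X1: np.ndarray,
    X2: np.ndarray,
    partition1: list[str],
    partition2: list[str],
    node_order1: list[NodeRef],
    node_order2: list[NodeRef],
    *,
    layer_order1: list[str] | None = None,
    layer_order2: list[str] | None = None,
    empty_value: float = 1.0,
    match_layers: str = "positional",
    use_signed_split: bool = True,
) -> SimilarityMatrix:
    """Score every same-layer (source, target) node pair.

    Layer correspondence is positional by default — layer i of the source
    network pairs with layer i of the target — so the two networks must
    expose the same number of layers.  ``match_layers='label'`` pairs
    layers by label instead.  With ``use_signed_split`` (default) each
    embedding is decomposed as ``[x+, (-x)+]`` before the weighted
    Jaccard, so negative components contribute to the score instead of
    being clipped away; on non-negative embeddings this changes nothing.
    """
    if np.isnan(X1).any() or np.isnan(X2).any():
        raise ValueError("NaN in embeddings")
    if use_signed_split:
        X1 = signed_split(X1)
        X2 = signed_split(X2)
    order1 = layer_order1 or list(dict.fromkeys(partition1))
    order2 = layer_order2 or list(dict.fromkeys(partition2))
    if match_layers == "label":
        if set(order1) != set(order2):
            raise ValueError("label matching requires identical layer label sets")
        pairs = [(lab, lab) for lab in order1]
    else:
        if len(order1) != len(order2):
            raise ValueError(
                f"source and target must have the same number of layers "
                f"({len(order1)} vs {len(order2)})"
            )
        pairs = list(zip(order1, order2))

    blocks: list[LayerBlock] = []
    for lay1, lay2 in pairs:
        rows1 = [i for i, lab in enumerate(partition1) if lab == lay1]
        rows2 = [j for j, lab in enumerate(partition2) if lab == lay2]
        values = _rectified_block(X1[rows1], X2[rows2], empty_value)
        blocks.append(
            LayerBlock(
                layer=lay1,
                source_order=[node_order1[i] for i in rows1],
                target_order=[node_order2[j] for j in rows2],
                values=values,
            )
        )
    return SimilarityMatrix(blocks=blocks)


def similarity_from_batches(batch1, batch2, X1, X2, **kwargs) -> SimilarityMatrix:
    """Convenience wrapper taking :class:`~mulsim.preprocess.GraphBatch` pairs."""
    return similarity_matrix(
        X1,
        X2,
        batch1.layer_partition,
        batch2.layer_partition,
        batch1.node_order,
        batch2.node_order,
        **kwargs,
    )
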