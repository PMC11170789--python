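"""Graph Isomorphism Network forward pass.

The per-step update is the GIN rule

    h_v <- MLP((1 + eps) * h_v + sum_{u in N(v)} h_u)

where the MLP is two linear maps with a ReLU between them and eps is a
per-step scalar.  The stack is conv1 (d_in -> d_hid), a list of
intermediate steps convs (d_hid -> d_hid, one per layer of the multilayer
network of interest), and conv2 (d_hid -> d_out); embeddings are the
output of the final step, so the total number of aggregation iterations
is K = 2 + len(convs).

No training objective is attached: the model is a seeded, randomly
initialized structural feature extractor.  Random-weight GINs retain the
architecture's discriminative power for isomorphism-style distinctions
(two 1-WL-distinguishable neighbourhoods map to different embeddings with
probability 1 under continuous weight distributions), which is all the
downstream similarity scoring needs.  Externally trained parameters can
be loaded via the JSON round-trip helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .preprocess import GraphBatch

__all__ = [
    "MLPParams",
    "GINLayerParams",
    "GINModel",
    "mlp_forward",
    "gin_layer_forward",
    "init_model",
    "embed",
    "embed_pair",
    "save_model",
    "load_model",
]


@dataclass
class MLPParams:
    """Two-linear-layer perceptron: ``x @ W1 + b1 -> ReLU -> @ W2 + b2``."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        if self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError("MLP hidden dimensions do not chain")
        if self.b1.shape != (self.W1.shape[1],) or self.b2.shape != (self.W2.shape[1],):
            raise ValueError("bias shapes inconsistent with weight matrices")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite MLP parameters")


@dataclass
class GINLayerParams:
    """One aggregation step: an MLP plus the learnable scalar eps (init 0)."""

    mlp: MLPParams
    epsilon: float = 0.0


@dataclass
class GINModel:
    """conv1 / convs / conv2 parameter stack shared across both networks."""

    conv1: GINLayerParams
    convs: list[GINLayerParams] = field(default_factory=list)
    conv2: GINLayerParams = None  # type: ignore[assignment]
    seed: int = 0

    @property
    def d_in(self) -> int:
        return self.conv1.mlp.W1.shape[0]

    @property
    def d_out(self) -> int:
        return self.conv2.mlp.W2.shape[1]

    @property
    def n_steps(self) -> int:
        """K, the number of aggregation iterations."""
        return 2 + len(self.convs)


def mlp_forward(params: MLPParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} != MLP d_in {params.W1.shape[0]}"
        )
    hidden = np.maximum(X @ params.W1 + params.b1, 0.0)
    return hidden @ params.W2 + params.b2


def gin_layer_forward(
    params: GINLayerParams, X: np.ndarray, edge_index: np.ndarray
) -> np.ndarray:
    """One GIN aggregation step over all nodes at once.

    ``edge_index`` holds directed (src, dst) columns; messages flow
    src -> dst unmodified and are summed.  Nodes with no in-edges keep
    only their own ``(1 + eps)``-scaled state.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite node features")
    agg = (1.0 + params.epsilon) * X
    if edge_index.size:
        if edge_index.max() >= X.shape[0] or edge_index.min() < 0:
            raise ValueError("edge_index references invalid row positions")
        np.add.at(agg, edge_index[1], X[edge_index[0]])
    return mlp_forward(params.mlp, agg)


def _orthogonal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """(Semi-)orthogonal matrix: SVD of a Gaussian draw.

    Orthogonal maps are norm-preserving, which keeps signal magnitudes
    stable through a deep *untrained* stack — compositions of generic
    random matrices with ReLU progressively collapse representations
    toward a dominant direction, degrading the embeddings' ability to
    discriminate nodes.
    """
    A = rng.normal(size=(fan_in, fan_out))
    U, _, Vt = np.linalg.svd(A, full_matrices=False)
    return U @ Vt


def _init_layer(rng: np.random.Generator, d_in: int, d_hid: int, d_out: int) -> GINLayerParams:
    return GINLayerParams(
        mlp=MLPParams(
            W1=_orthogonal(rng, d_in, d_hid),
            b1=np.zeros(d_hid),
            W2=_orthogonal(rng, d_hid, d_out),
            b2=np.zeros(d_out),
        ),
        epsilon=0.0,
    )


def init_model(
    d_in: int,
    d_hid: int,
    d_out: int,
    n_intermediate: int,
    seed: int,
) -> GINModel:
    """Deterministically initialize a GIN stack.

    ``n_intermediate`` is the number of convs steps — one per layer of the
    multilayer network being analysed.  Weight matrices are (semi-)
    orthogonal, drawn from a Philox counter-based stream keyed by
    ``seed``; biases and every eps start at 0, and two calls with equal
    arguments are bitwise identical.
    """
    if n_intermediate < 1:
        raise ValueError("need at least one intermediate step (one per network layer)")
    if min(d_in, d_hid, d_out) < 1:
        raise ValueError("channel counts must be positive")
    rng = np.random.Generator(np.random.Philox(key=seed))
    conv1 = _init_layer(rng, d_in, d_hid, d_hid)
    convs = [_init_layer(rng, d_hid, d_hid, d_hid) for _ in range(n_intermediate)]
    conv2 = _init_layer(rng, d_hid, d_hid, d_out)
    return GINModel(conv1=conv1, convs=convs, conv2=conv2, seed=seed)


def _row_normalize(h: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    return np.where(norms > 0, h / np.maximum(norms, 1e-300), h)


def embed(
    model: GINModel, batch: GraphBatch, *, normalize_steps: bool = True
) -> np.ndarray:
    """Run the full stack; rows follow ``batch.node_order``.

    With ``normalize_steps`` (the default) every intermediate state is
    L2-normalized row-wise before the next aggregation.  Sum aggregation
    on dense graphs inflates magnitudes exponentially with depth; the
    per-node rescaling keeps the dynamic range bounded without changing
    which nodes are distinguishable (equal rows stay equal, and the final
    conv2 output is left unnormalized).
    """
    if batch.features.shape[1] != model.d_in:
        raise ValueError(
            f"batch width {batch.features.shape[1]} != model d_in {model.d_in}"
        )
    h = gin_layer_forward(model.conv1, batch.features, batch.edge_index)
    for layer in model.convs:
        if normalize_steps:
            h = _row_normalize(h)
        h = gin_layer_forward(layer, h, batch.edge_index)
    if normalize_steps:
        h = _row_normalize(h)
    return gin_layer_forward(model.conv2, h, batch.edge_index)


def embed_pair(
    model: GINModel,
    batch_source: GraphBatch,
    batch_target: GraphBatch,
    *,
    normalize_steps: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed both networks with the same parameters (no per-network refit)."""
    return (
        embed(model, batch_source, normalize_steps=normalize_steps),
        embed(model, batch_target, normalize_steps=normalize_steps),
    )


# ---------------------------------------------------------------------------
# parameter persistence (JSON of arrays — portable, text-only)
# ---------------------------------------------------------------------------

def _layer_to_obj(layer: GINLayerParams) -> dict:
    return {
        "W1": layer.mlp.W1.tolist(),
        "b1": layer.mlp.b1.tolist(),
        "W2": layer.mlp.W2.tolist(),
        "b2": layer.mlp.b2.tolist(),
        "epsilon": layer.epsilon,
    }


def _layer_from_obj(obj: dict) -> GINLayerParams:
    return GINLayerParams(
        mlp=MLPParams(
            W1=np.asarray(obj["W1"], dtype=np.float64),
            b1=np.asarray(obj["b1"], dtype=np.float64),
            W2=np.asarray(obj["W2"], dtype=np.float64),
            b2=np.asarray(obj["b2"], dtype=np.float64),
        ),
        epsilon=float(obj["epsilon"]),
    )


def save_model(model: GINModel, stream: IO[str]) -> None:
    json.dump(
        {
            "seed": model.seed,
            "conv1": _layer_to_obj(model.conv1),
            "convs": [_layer_to_obj(c) for c in model.convs],
            "conv2": _layer_to_obj(model.conv2),
        },
        stream,
    )


def load_model(stream: IO[str]) -> GINModel:
    obj = json.load(stream)
    return GINModel(
        conv1=_layer_from_obj(obj["conv1"]),
        convs=[_layer_from_obj(c) for c in obj["convs"]],
        conv2=_layer_from_obj(obj["conv2"]),
        seed=int(obj["seed"]),
    )
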