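"""Scikit-learn-style estimator interfaces over the similarity pipeline.

Two estimators are exposed:

* :class:`GINEmbedder` — a transformer: ``fit`` initializes the shared,
  seeded GIN parameters (sized from the network's layer count and the
  configured channel widths) and ``transform`` embeds a multilayer
  network into per-node vectors.
* :class:`PairwiseNodeSimilarity` — the end-to-end scorer: ``fit`` takes
  a (source, target) pair of multilayer networks, embeds both with one
  shared parameter set, and exposes the layer-blocked similarity matrix
  as ``similarity_``; ``predict`` returns the node mapping obtained from
  it.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores), so they compose with sklearn
tooling; the functional modules remain the primitives underneath.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator, TransformerMixin

from . import alignval, gin, preprocess, simscore
from .netio import MultilayerNetwork

__all__ = ["GINEmbedder", "PairwiseNodeSimilarity"]


class GINEmbedder(TransformerMixin, BaseEstimator):
    """Embed multilayer-network nodes with a seeded, untrained GIN.

    Parameters
    ----------
    input_channels : int, default=64
        Width of the topological initial feature vectors.
    hidden_channels, output_channels : int or None
        GIN widths; ``None`` means equal to ``input_channels``.
    n_intermediate : int or None
        Number of intermediate aggregation steps; ``None`` ties it to the
        number of layers of the network passed to ``fit``.
    random_state : int, default=0
        Seed of the deterministic parameter initialization.

    Attributes
    ----------
    model_ : GINModel
        The initialized parameter stack, shared by every ``transform``.
    """

    def __init__(
        self,
        input_channels: int = 64,
        hidden_channels: int | None = None,
        output_channels: int | None = None,
        n_intermediate: int | None = None,
        random_state: int = 0,
    ):
        self.input_channels = input_channels
        self.hidden_channels = hidden_channels
        self.output_channels = output_channels
        self.n_intermediate = n_intermediate
        self.random_state = random_state

    def fit(self, X: MultilayerNetwork, y=None):
        if self.input_channels < 2:
            raise ValueError("input_channels must be >= 2")
        n_inter = self.n_intermediate if self.n_intermediate is not None else X.n_layers
        self.model_ = gin.init_model(
            d_in=self.input_channels,
            d_hid=self.hidden_channels or self.input_channels,
            d_out=self.output_channels or self.input_channels,
            n_intermediate=n_inter,
            seed=self.random_state,
        )
        return self

    def transform(self, X: MultilayerNetwork):
        """Return the embedding batch: (GraphBatch, embeddings array)."""
        batch = preprocess.prepare(X, d=self.input_channels)
        return batch, gin.embed(self.model_, batch)


class PairwiseNodeSimilarity(BaseEstimator):
    """Cross-network node similarity with layer-on-layer scoring.

    ``fit`` accepts ``X=(source, target)``, two multilayer networks with
    equal layer counts.  Both are embedded with the same GIN parameters
    and every same-layer node pair is scored with the weighted Jaccard
    coefficient; the result is stored as ``similarity_``.  ``predict``
    returns the per-layer maximum-weight-matching node mapping.
    """

    def __init__(
        self,
        input_channels: int = 64,
        hidden_channels: int | None = None,
        output_channels: int | None = None,
        random_state: int = 0,
        empty_value: float = 1.0,
        align_method: str = "matching",
    ):
        self.input_channels = input_channels
        self.hidden_channels = hidden_channels
        self.output_channels = output_channels
        self.random_state = random_state
        self.empty_value = empty_value
        self.align_method = align_method

    def fit(self, X, y=None):
        source, target = X
        if source.n_layers != target.n_layers:
            raise ValueError(
                "source and target must have the same number of layers "
                f"({source.n_layers} vs {target.n_layers})"
            )
        embedder = GINEmbedder(
            input_channels=self.input_channels,
            hidden_channels=self.hidden_channels,
            output_channels=self.output_channels,
            n_intermediate=source.n_layers,
            random_state=self.random_state,
        ).fit(source)
        self.embedder_ = embedder
        batch1, emb1 = embedder.transform(source)
        batch2, emb2 = embedder.transform(target)
        self.batch_source_, self.batch_target_ = batch1, batch2
        self.embeddings_source_, self.embeddings_target_ = emb1, emb2
        self.similarity_ = simscore.similarity_matrix(
            emb1,
            emb2,
            batch1.layer_partition,
            batch2.layer_partition,
            batch1.node_order,
            batch2.node_order,
            layer_order1=source.layer_order,
            layer_order2=target.layer_order,
            empty_value=self.empty_value,
        )
        return self

    def predict(self, X=None) -> alignval.NodeMapping:
        """Node mapping from the fitted similarity matrix."""
        return alignval.align(self.similarity_, method=self.align_method)

    def score(self, X=None, y: alignval.NodeMapping | None = None) -> float:
        """Node Correctness of ``predict`` against a ground-truth mapping."""
        if y is None:
            raise ValueError("score requires a ground-truth NodeMapping")
        return alignval.node_correctness(self.predict(), y)
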