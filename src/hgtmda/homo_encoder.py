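"""Attention-enhanced GCN over the masked multi-view similarity networks.

Each similarity view of an entity type is encoded by its own two-layer GCN
(symmetric normalisation with self-loops, ReLU); the per-view embeddings are
then fused by a per-node softmax attention over views, so the model can
down-weight noisy or uninformative views node by node.

Node input features are the node's similarity profile (its row of the view
matrix) projected through a learned linear map shared across the views of one
entity type, and each propagation layer carries an identity residual. Both
choices counter over-smoothing: similarity networks are dense and near-uniform
after degree normalisation, so pure neighbourhood averaging would collapse
node-specific geometry within two layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat, glorot

__all__ = ["ViewEmbeddings", "sym_norm_adj", "gcn_view_encode",
           "attention_fuse_views", "MultiViewGCN"]


@dataclass
class ViewEmbeddings:
    per_view: dict[str, np.ndarray]
    fused: np.ndarray
    attention_weights: np.ndarray  # n x n_views, rows on the simplex


def sym_norm_adj(A: np.ndarray) -> np.ndarray:
    """D^-1/2 (A + I) D^-1/2 with self-loops (numpy, no gradient)."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    Ah = A + np.eye(A.shape[0])
    d = Ah.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * Ah * dinv[None, :]


def gcn_view_encode(A_mask: np.ndarray, X0: np.ndarray,
                    weights: list[np.ndarray]) -> np.ndarray:
    """Deterministic GCN forward pass H <- relu(Ahat H W) per layer."""
    A_mask = np.asarray(A_mask, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    if X0.shape[0] != A_mask.shape[0]:
        raise ValueError("X0 rows must match adjacency dimension")
    if not weights:
        raise ValueError("need at least one layer weight")
    Ahat = sym_norm_adj(A_mask)
    H = X0
    for W in weights:
        H = np.maximum(Ahat @ H @ np.asarray(W, dtype=float), 0.0)
    return H


def attention_fuse_views(per_view: dict[str, np.ndarray],
                         score_vector: np.ndarray | None = None) -> ViewEmbeddings:
    """Fuse per-view embeddings with per-node softmax weights over views.

    Scores are H_v @ a for a shared scoring vector a (zeros by default, which
    yields uniform weights). A single view gets weight 1 exactly.
    """
    names = list(per_view)
    mats = [np.asarray(per_view[k], dtype=float) for k in names]
    if not mats:
        raise ValueError("need at least one view")
    shape = mats[0].shape
    for k, M in zip(names, mats):
        if M.shape != shape:
            raise ValueError(f"view {k}: shape mismatch {M.shape} != {shape}")
    n, dim = shape
    a = np.zeros(dim) if score_vector is None else np.asarray(score_vector, float)
    logits = np.stack([M @ a for M in mats], axis=1)  # n x V
    z = logits - logits.max(axis=1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)
    fused = sum(w[:, [v]] * mats[v] for v in range(len(mats)))
    return ViewEmbeddings(dict(zip(names, mats)), fused, w)


class MultiViewGCN:
    """Trainable multi-view GCN encoder with view-attention fusion."""

    def __init__(self, n_nodes: int, view_names, dim: int = 128,
                 layers: int = 2, dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        if layers < 1:
            raise ValueError("layers must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.view_names = list(view_names)
        self.dim, self.layers, self.dropout = dim, layers, dropout
        self.embed = glorot(rng, n_nodes, dim)
        self.weights = {v: [glorot(rng, dim, dim) for _ in range(layers)]
                        for v in self.view_names}
        self.score_vec = Tensor(np.zeros((dim, 1)), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        ps = [self.embed, self.score_vec]
        for v in self.view_names:
            ps.extend(self.weights[v])
        return ps

    def forward(self, masked_views: dict[str, np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (fused Tensor n x dim, per-view Tensors, weight Tensor n x V)."""
        per_view = []
        for v in self.view_names:
            Ahat = Tensor(sym_norm_adj(masked_views[v]))
            H = Tensor(masked_views[v]) @ self.embed  # similarity-profile features
            for W in self.weights[v]:
                H = (Ahat @ H @ W).relu() + H
                if training and self.dropout > 0 and rng is not None:
                    keep = (rng.random(H.shape) >= self.dropout) / (1 - self.dropout)
                    H = H * Tensor(keep)
            per_view.append(H)
        logits = concat([H @ self.score_vec for H in per_view], axis=1)
        w = logits.softmax(axis=1)  # n x V
        fused = None
        for v, H in enumerate(per_view):
            term = w[:, [v]] * H
            fused = term if fused is None else fused + term
        return fused, per_view, w
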