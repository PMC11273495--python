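"""Supernode heterogeneous hypergraph and shortest-path-biased GCN-Transformer.

A bank of q learned supernodes mediates cross-type information flow: each
supernode is connected to every miRNA and disease node with a weight given by
the (ReLU-clipped) cosine similarity between the node embedding and the
supernode embedding. Known train-time associations connect miRNA and disease
nodes directly with weight 1; no other direct edges exist. The hypergraph is
realised as an ordinary weighted graph over km+kd+q nodes.

The encoder stacks layers that combine a GCN sublayer (symmetric normalisation
with self-loops) with multi-head self-attention whose logits carry an additive
shortest-path bias, followed by residual + LayerNorm and a position-wise
feed-forward block. Two bias modes exist: ``embedding`` (default) uses a
learnable scalar per integer hop distance, initialised decreasing so nearby
nodes receive more attention; ``raw`` adds the hop count itself to the logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from ._autograd import Tensor, concat, glorot

__all__ = [
    "GCTConfig",
    "HypergraphBundle",
    "cosine_weights",
    "assemble_hypergraph",
    "shortest_path_matrix",
    "sp_biased_attention",
    "GCTEncoder",
]


@dataclass
class GCTConfig:
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 128
    ffn_hidden: int = 2048
    max_sp: int = 8
    supernodes: int = 64
    dropout: float = 0.5
    bias_mode: str = "embedding"  # embedding | raw

    def __post_init__(self):
        for name in ("n_layers", "n_heads", "d_model", "ffn_hidden", "max_sp",
                     "supernodes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_model % self.n_heads != 0:
            raise ValueError("n_heads must divide d_model")
        if self.bias_mode not in ("embedding", "raw"):
            raise ValueError("bias_mode must be 'embedding' or 'raw'")


@dataclass
class HypergraphBundle:
    Xm: np.ndarray
    Xd: np.ndarray
    Q: np.ndarray
    C_mq: np.ndarray
    C_dq: np.ndarray
    A_hyper: np.ndarray

    @property
    def sizes(self) -> tuple[int, int, int]:
        return self.Xm.shape[0], self.Xd.shape[0], self.Q.shape[0]


# ---------------------------------------------------------------------------
# hypergraph assembly

def cosine_weights(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity X_i . Q_k / (||X_i|| ||Q_k||).

    Zero-norm rows get weight 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if X.shape[1] != Q.shape[1]:
        raise ValueError("embedding dimensions disagree")
    nx = np.linalg.norm(X, axis=1)
    nq = np.linalg.norm(Q, axis=1)
    C = X @ Q.T
    denom = np.outer(nx, nq)
    out = np.zeros_like(C)
    nz = denom > 0
    out[nz] = C[nz] / denom[nz]
    return np.clip(out, -1.0, 1.0)


def cosine_weights_t(X: Tensor, Q: Tensor, eps: float = 1e-12) -> Tensor:
    """Differentiable cosine weights (Tensor version used in training)."""
    nx = ((X * X).sum(axis=1, keepdims=True) + eps) ** 0.5
    nq = ((Q * Q).sum(axis=1, keepdims=True) + eps) ** 0.5
    return (X / nx) @ (Q / nq).T


def assemble_hypergraph(Xm: np.ndarray, Xd: np.ndarray, Q: np.ndarray,
                        known_pairs, forbidden_pairs=None) -> HypergraphBundle:
    """Assemble the (km+kd+q)^2 adjacency from embeddings and train positives.

    Blocks: miRNA-supernode = ReLU(cosine), disease-supernode = ReLU(cosine),
    miRNA-disease = known (training) associations at weight 1, zero elsewhere.
    ``forbidden_pairs`` (e.g. the test set) must not appear in ``known_pairs``.
    """
    Xm, Xd, Q = (np.asarray(M, dtype=float) for M in (Xm, Xd, Q))
    km, kd, q = Xm.shape[0], Xd.shape[0], Q.shape[0]
    known = {(int(i), int(j)) for i, j in known_pairs}
    if forbidden_pairs is not None:
        leak = known & {(int(i), int(j)) for i, j in forbidden_pairs}
        if leak:
            raise ValueError(f"test pairs leaked into hypergraph edges: {sorted(leak)[:5]}")
    C_mq = cosine_weights(Xm, Q)
    C_dq = cosine_weights(Xd, Q)
    A = np.zeros((km + kd + q, km + kd + q))
    for i, j in known:
        A[i, km + j] = A[km + j, i] = 1.0
    A[:km, km + kd:] = np.maximum(C_mq, 0.0)
    A[km + kd:, :km] = np.maximum(C_mq, 0.0).T
    A[km:km + kd, km + kd:] = np.maximum(C_dq, 0.0)
    A[km + kd:, km:km + kd] = np.maximum(C_dq, 0.0).T
    return HypergraphBundle(Xm, Xd, Q, C_mq, C_dq, A)


def shortest_path_matrix(A_hyper: np.ndarray, max_sp: int = 8) -> np.ndarray:
    """Integer hop distances on the unweighted support, capped at max_sp.

    Unreachable pairs (and anything beyond the cap) get max_sp; the diagonal
    is 0.
    """
    A = np.asarray(A_hyper)
    support = csr_matrix((A > 0).astype(np.int8))
    D = _csgraph_sp(support, method="D", directed=False, unweighted=True)
    D[~np.isfinite(D)] = max_sp
    return np.minimum(D, max_sp).astype(np.int64)


# ---------------------------------------------------------------------------
# shortest-path-biased attention

def sp_biased_attention(H: np.ndarray, weights, Dphi: np.ndarray,
                        bias: np.ndarray | None = None):
    """Single forward pass of multi-head SP-biased attention (numpy).

    ``weights`` is a list of (WQ, WK, WV) triples, one per head. ``bias``
    defaults to the raw distance matrix added to the logits (the literal
    additive form); pass a precomputed bias matrix for other schemes.
    Returns (concatenated head outputs, list of attention matrices).
    """
    H = np.asarray(H, dtype=float)
    if np.isnan(H).any():
        raise ValueError("NaN in attention input")
    Dphi = np.asarray(Dphi, dtype=float)
    if Dphi.shape != (H.shape[0], H.shape[0]):
        raise ValueError("distance matrix shape mismatch")
    B = Dphi if bias is None else np.asarray(bias, dtype=float)
    outs, attns = [], []
    for WQ, WK, WV in weights:
        Q, K, V = H @ WQ, H @ WK, H @ WV
        dk = Q.shape[1]
        logits = Q @ K.T / np.sqrt(dk) + B
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        attn = e / e.sum(axis=1, keepdims=True)
        outs.append(attn @ V)
        attns.append(attn)
    return np.concatenate(outs, axis=1), attns


# ---------------------------------------------------------------------------
# trainable encoder

class GCTEncoder:
    """Stacked GCN + SP-biased multi-head attention encoder (trainable)."""

    def __init__(self, cfg: GCTConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        E, L = cfg.d_model, cfg.n_layers
        self.Wg = [glorot(rng, E, E) for _ in range(L)]
        self.WQ = [glorot(rng, E, E) for _ in range(L)]
        self.WK = [glorot(rng, E, E) for _ in range(L)]
        self.WV = [glorot(rng, E, E) for _ in range(L)]
        self.WO = [glorot(rng, E, E) for _ in range(L)]
        # learnable scalar bias per hop distance, per layer and head,
        # initialised decreasing in distance (locality prior)
        init = -0.5 * np.arange(cfg.max_sp + 1, dtype=float)
        self.dist_bias = [[Tensor(init.copy(), requires_grad=True)
                           for _ in range(cfg.n_heads)] for _ in range(L)]
        self.ln_g = [[Tensor(np.ones(E), requires_grad=True) for _ in range(2)]
                     for _ in range(L)]
        self.ln_b = [[Tensor(np.zeros(E), requires_grad=True) for _ in range(2)]
                     for _ in range(L)]
        self.W1 = [glorot(rng, E, cfg.ffn_hidden) for _ in range(L)]
        self.b1 = [Tensor(np.zeros(cfg.ffn_hidden), requires_grad=True) for _ in range(L)]
        self.W2 = [glorot(rng, cfg.ffn_hidden, E) for _ in range(L)]
        self.b2 = [Tensor(np.zeros(E), requires_grad=True) for _ in range(L)]
        self.last_attention: list[list[np.ndarray]] = []

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for lst in (self.Wg, self.WQ, self.WK, self.WV, self.WO, self.W1,
                    self.b1, self.W2, self.b2):
            ps.extend(lst)
        for layer in self.dist_bias:
            ps.extend(layer)
        for layer in self.ln_g:
            ps.extend(layer)
        for layer in self.ln_b:
            ps.extend(layer)
        return ps

    @staticmethod
    def _norm_adj_t(A: Tensor) -> Tensor:
        n = A.shape[0]
        Ah = A + Tensor(np.eye(n))
        d = Ah.sum(axis=1, keepdims=True)
        dinv = d ** -0.5
        return dinv * Ah * dinv.T

    def _dropout(self, H: Tensor, training: bool, rng) -> Tensor:
        p = self.cfg.dropout
        if training and p > 0 and rng is not None:
            keep = (rng.random(H.shape) >= p) / (1 - p)
            return H * Tensor(keep)
        return H

    def layer_forward(self, H: Tensor, Ahat: Tensor, Dphi: np.ndarray,
                      layer: int, training: bool = False, rng=None,
                      plain_gcn: bool = False) -> Tensor:
        cfg = self.cfg
        # identity residual on the GCN sublayer: the supernode graph is dense,
        # so un-skipped averaging would erase node-specific features
        Hg = (Ahat @ H @ self.Wg[layer]).relu() + H
        Hg = self._dropout(Hg, training, rng)
        if plain_gcn:
            return Hg
        n = Hg.shape[0]
        dh = cfg.d_model // cfg.n_heads
        Q = Hg @ self.WQ[layer]
        K = Hg @ self.WK[layer]
        V = Hg @ self.WV[layer]
        Dcap = np.minimum(Dphi, cfg.max_sp)
        heads, attns = [], []
        for h in range(cfg.n_heads):
            sl = (slice(None), slice(h * dh, (h + 1) * dh))
            Qh, Kh, Vh = Q[sl], K[sl], V[sl]
            if cfg.bias_mode == "embedding":
                bias = self.dist_bias[layer][h].take(Dcap)
            else:
                bias = Tensor(Dcap.astype(float))
            logits = Qh @ Kh.T * (1.0 / np.sqrt(dh)) + bias
            attn = logits.softmax(axis=-1)
            attns.append(attn.data)
            heads.append(attn @ Vh)
        attn_out = concat(heads, axis=1) @ self.WO[layer]
        attn_out = self._dropout(attn_out, training, rng)
        self.last_attention.append(attns)
        H1 = (Hg + attn_out).layer_norm() * self.ln_g[layer][0] + self.ln_b[layer][0]
        F = (H1 @ self.W1[layer] + self.b1[layer]).relu()
        F = self._dropout(F, training, rng)
        F = F @ self.W2[layer] + self.b2[layer]
        return (H1 + F).layer_norm() * self.ln_g[layer][1] + self.ln_b[layer][1]

    def forward(self, H0: Tensor, A_hyper: Tensor, Dphi: np.ndarray,
                training: bool = False, rng=None, plain_gcn: bool = False) -> Tensor:
        self.last_attention = []
        Ahat = self._norm_adj_t(A_hyper)
        H = H0
        for layer in range(self.cfg.n_layers):
            H = self.layer_forward(H, Ahat, Dphi, layer, training, rng, plain_gcn)
        return H

    def encode(self, Xm: Tensor, Xd: Tensor, Q: Tensor, A_hyper: Tensor,
               Dphi: np.ndarray, training: bool = False, rng=None,
               plain_gcn: bool = False) -> tuple[Tensor, Tensor]:
        """Jointly encode all node families; return (Zm, Zd) (supernode rows
        are updated internally but not returned)."""
        km, kd = Xm.shape[0], Xd.shape[0]
        H0 = concat([Xm, Xd, Q], axis=0)
        H = self.forward(H0, A_hyper, Dphi, training, rng, plain_gcn)
        return H[:km], H[km:km + kd]
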