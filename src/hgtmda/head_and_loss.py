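"""Pair-scoring head and the combined Dice + cross-entropy (DCE) loss.

Each entity's two representation sources (multi-view homogeneous embedding
and hypergraph encoder output) are integrated with a learned two-way softmax
attention; the integrated miRNA and disease vectors pass through a shared 1-D
convolution, their Hadamard product feeds a single-layer feed-forward network
with a sigmoid, giving the association probability.

The training objective is L = alpha * L_Dice + (1 - alpha) * L_CE: the Dice
term rewards overlap between the predicted score mass and the positive set
(robust to class imbalance), the cross-entropy term matches the predicted and
true label distributions. alpha defaults to 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, glorot

__all__ = ["PairScore", "LossConfig", "PairHead", "score_pairs",
           "dice_loss", "ce_loss", "dce_loss", "dice_loss_t", "ce_loss_t",
           "dce_loss_t"]

CE_EPS = 1e-7


@dataclass
class PairScore:
    mirna_index: int
    disease_index: int
    y_hat: float
    y: int | None = None


@dataclass
class LossConfig:
    alpha: float = 0.8
    smooth_eps: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if self.smooth_eps < 0:
            raise ValueError("smooth_eps must be >= 0")


# ---------------------------------------------------------------------------
# losses — single implementation on tensors, numpy wrappers on top

def dice_loss_t(y: np.ndarray, y_hat: Tensor, smooth_eps: float = 0.0) -> Tensor:
    """L_Dice = 1 - (2 sum(y*yhat) + eps) / (sum(y) + sum(yhat) + eps)."""
    y = np.asarray(y, dtype=float)
    denom_val = y.sum() + float(np.sum(y_hat.data))
    if denom_val == 0 and smooth_eps == 0:
        raise ValueError("sum(y) + sum(y_hat) = 0: Dice undefined without "
                         "a smoothing eps")
    num = (Tensor(y) * y_hat).sum() * 2.0 + smooth_eps
    den = (Tensor(y).sum() + y_hat.sum()) + smooth_eps
    return 1.0 - num / den


def ce_loss_t(y: np.ndarray, y_hat: Tensor) -> Tensor:
    """Mean binary cross-entropy with scores clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != y_hat.shape[0]:
        raise ValueError("label / score length mismatch")
    p = y_hat.clip(CE_EPS, 1.0 - CE_EPS)
    t = Tensor(y)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def dce_loss_t(y: np.ndarray, y_hat: Tensor, cfg: LossConfig) -> Tensor:
    a = cfg.alpha
    if a == 0.0:
        return ce_loss_t(y, y_hat)
    if a == 1.0:
        return dice_loss_t(y, y_hat, cfg.smooth_eps)
    return a * dice_loss_t(y, y_hat, cfg.smooth_eps) + (1.0 - a) * ce_loss_t(y, y_hat)


def dice_loss(y, y_hat, smooth_eps: float = 0.0) -> float:
    y_hat = np.asarray(y_hat, dtype=float)
    if np.any((y_hat < 0) | (y_hat > 1)):
        raise ValueError("scores must lie in [0,1]")
    return float(dice_loss_t(y, Tensor(y_hat), smooth_eps).data)


def ce_loss(y, y_hat) -> float:
    return float(ce_loss_t(y, Tensor(np.asarray(y_hat, dtype=float))).data)


def dce_loss(y, y_hat, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    return float(dce_loss_t(y, Tensor(np.asarray(y_hat, dtype=float)), cfg).data)


# ---------------------------------------------------------------------------
# scoring head

def score_pairs(Zm: np.ndarray, Zd: np.ndarray, pairs, head_weights: dict) -> list[PairScore]:
    """Score (miRNA, disease) pairs from final embeddings (numpy, no grad).

    head_weights: {"conv": (K,) kernel, "w": (E,) FNN weights, "b": scalar}.
    """
    Zm = np.asarray(Zm, dtype=float)
    Zd = np.asarray(Zd, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size and (pairs[:, 0].max() >= Zm.shape[0]
                       or pairs[:, 1].max() >= Zd.shape[0]):
        raise IndexError("pair index out of range")
    conv = np.asarray(head_weights["conv"], dtype=float)
    w = np.asarray(head_weights["w"], dtype=float)
    b = float(head_weights["b"])
    M = Tensor(Zm[pairs[:, 0]]).conv1d_same(Tensor(conv)).data
    D = Tensor(Zd[pairs[:, 1]]).conv1d_same(Tensor(conv)).data
    logits = (M * D) @ w + b
    # keep probabilities strictly inside (0,1) despite float saturation
    probs = np.clip(1.0 / (1.0 + np.exp(-logits)), 1e-12, 1.0 - 1e-12)
    return [PairScore(int(i), int(j), float(p))
            for (i, j), p in zip(pairs, probs)]


class PairHead:
    """Trainable scoring head with source-integration attention."""

    def __init__(self, dim: int, conv_kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if conv_kernel % 2 != 1:
            raise ValueError("conv kernel length must be odd")
        self.fuse_m = Tensor(np.zeros(2), requires_grad=True)
        self.fuse_d = Tensor(np.zeros(2), requires_grad=True)
        kern = np.zeros(conv_kernel)
        kern[conv_kernel // 2] = 1.0  # identity-initialised convolution
        self.conv_w = Tensor(kern, requires_grad=True)
        self.fnn_w = glorot(rng, dim, 1)
        self.fnn_b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.fuse_m, self.fuse_d, self.conv_w, self.fnn_w, self.fnn_b]

    def integrate(self, homo: Tensor, gct: Tensor, logits: Tensor) -> Tensor:
        w = logits.softmax(axis=-1)
        return w[0] * homo + w[1] * gct

    def forward(self, Xm: Tensor, Zm: Tensor, Xd: Tensor, Zd: Tensor,
                pairs: np.ndarray) -> Tensor:
        pairs = np.asarray(pairs, dtype=int)
        m_hat = self.integrate(Xm, Zm, self.fuse_m)
        d_hat = self.integrate(Xd, Zd, self.fuse_d)
        M = m_hat[pairs[:, 0]].conv1d_same(self.conv_w)
        D = d_hat[pairs[:, 1]].conv1d_same(self.conv_w)
        logits = (M * D) @ self.fnn_w + self.fnn_b
        return logits.sigmoid().reshape(-1)
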