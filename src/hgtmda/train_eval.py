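"""End-to-end training, cross-validation, metrics, ablations, ranking.

Per training epoch the pipeline: (1) resamples RWR association masks on every
similarity view, (2) encodes each entity type with the attention-enhanced
multi-view GCN, (3) assembles the supernode hypergraph from *training*
positives only, (4) runs the shortest-path-biased GCN-Transformer encoder,
(5) scores the training pairs and steps Adam on the DCE loss. Evaluation
reuses the trained weights with unmasked views and dropout off.

Ablation variants (all reachable from config alone):
  HGT-A  masking removed (A_mask = A)
  HGT-B  masking without restart (c = 0)
  HGT-C  plain GCN replaces the GCN-Transformer encoder
  HGT-D  plain BCE replaces the DCE loss (alpha = 0)
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)

from ._autograd import Adam, Tensor, concat, set_grad_enabled
from .data_io import AssociationDataset, SplitSpec
from .head_and_loss import LossConfig, PairHead, dce_loss_t
from .homo_encoder import MultiViewGCN
from .hyper_gct import GCTConfig, GCTEncoder, cosine_weights_t, shortest_path_matrix
from .rwr_mask import MaskConfig, mask_graph
from .similarity import SimilarityViewSet

__all__ = ["ModelConfig", "EvalReport", "HGTModel", "TrainedModel", "train",
           "predict_scores", "evaluate", "cross_validate", "rank_candidates",
           "compute_metrics"]

ABLATIONS = ("full", "HGT-A", "HGT-B", "HGT-C", "HGT-D")
METRIC_NAMES = ("acc", "f1", "recall", "precision", "auc", "auprc")


@dataclass
class ModelConfig:
    """All hyperparameters; defaults follow the published configuration
    (4 attention heads, 2 GCN layers, max path 8, FFN 2048, mask ratio 0.3,
    restart 0.6, 64 supernodes, dropout 0.5, alpha 0.8)."""

    homo_dim: int = 128
    homo_layers: int = 2
    homo_dropout: float = 0.5
    mask: MaskConfig = field(default_factory=MaskConfig)
    gct: GCTConfig = field(default_factory=GCTConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    conv_kernel: int = 3
    lr: float = 1e-3
    epochs: int = 200
    weight_decay: float = 0.0
    ablation: str = "full"
    fixed_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        self.gct = replace(self.gct, d_model=self.homo_dim)

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 400, **overrides) -> "ModelConfig":
        """Configuration scaled to desk-size fixtures (~100 x 60 entities):
        smaller embedding, FFN and supernode bank, lighter dropout."""
        kw = dict(
            homo_dim=48,
            homo_dropout=0.1,
            gct=GCTConfig(ffn_hidden=256, supernodes=32, dropout=0.1, d_model=48),
            epochs=epochs,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def for_ablation(self, name: str) -> "ModelConfig":
        cfg = copy.deepcopy(self)
        cfg.ablation = name
        if name == "HGT-B":
            cfg.mask = replace(cfg.mask, c=0.0)
        if name == "HGT-D":
            cfg.loss = replace(cfg.loss, alpha=0.0)
        return cfg


@dataclass
class EvalReport:
    fold_metrics: list[dict]
    mean: dict

    @staticmethod
    def from_folds(fold_metrics: list[dict]) -> "EvalReport":
        mean = {k: float(np.mean([m[k] for m in fold_metrics]))
                for k in fold_metrics[0]}
        return EvalReport(fold_metrics, mean)


# ---------------------------------------------------------------------------
# model

class HGTModel:
    """The full trainable model: two multi-view GCN encoders, a learned
    supernode bank, the GCN-Transformer hypergraph encoder and the pair head."""

    def __init__(self, cfg: ModelConfig, km: int, kd: int,
                 m_view_names, d_view_names, rng: np.random.Generator):
        self.cfg = cfg
        self.km, self.kd = km, kd
        dim = cfg.homo_dim
        self.homo_m = MultiViewGCN(km, m_view_names, dim, cfg.homo_layers,
                                   cfg.homo_dropout, rng)
        self.homo_d = MultiViewGCN(kd, d_view_names, dim, cfg.homo_layers,
                                   cfg.homo_dropout, rng)
        self.Q = Tensor(rng.normal(0.0, 0.1, size=(cfg.gct.supernodes, dim)),
                        requires_grad=True)
        self.gct = GCTEncoder(cfg.gct, rng)
        self.head = PairHead(dim, cfg.conv_kernel, rng)

    @property
    def params(self) -> list[Tensor]:
        return (self.homo_m.params + self.homo_d.params + [self.Q]
                + self.gct.params + self.head.params)

    def _hyper_adjacency(self, Cm: Tensor, Cd: Tensor, A_md: np.ndarray):
        km, kd, q = self.km, self.kd, self.cfg.gct.supernodes
        Zmm = Tensor(np.zeros((km, km)))
        Zdd = Tensor(np.zeros((kd, kd)))
        Zqq = Tensor(np.zeros((q, q)))
        Amd = Tensor(A_md)
        top = concat([Zmm, Amd, Cm], axis=1)
        mid = concat([Amd.T, Zdd, Cd], axis=1)
        bot = concat([Cm.T, Cd.T, Zqq], axis=1)
        return concat([top, mid, bot], axis=0)

    def forward(self, m_views: dict[str, np.ndarray], d_views: dict[str, np.ndarray],
                A_md: np.ndarray, pairs: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        plain = self.cfg.ablation == "HGT-C"
        Xm, _, _ = self.homo_m.forward(m_views, training, rng)
        Xd, _, _ = self.homo_d.forward(d_views, training, rng)
        Cm = cosine_weights_t(Xm, self.Q).relu()
        Cd = cosine_weights_t(Xd, self.Q).relu()
        A_hyper = self._hyper_adjacency(Cm, Cd, A_md)
        Dphi = shortest_path_matrix(A_hyper.data, self.cfg.gct.max_sp)
        Zm, Zd = self.gct.encode(Xm, Xd, self.Q, A_hyper, Dphi,
                                 training, rng, plain_gcn=plain)
        return self.head.forward(Xm, Zm, Xd, Zd, pairs)


@dataclass
class TrainedModel:
    model: HGTModel
    cfg: ModelConfig
    loss_trajectory: list[float]
    A_md: np.ndarray  # train-positive bipartite block used in the hypergraph
    m_views: dict[str, np.ndarray]
    d_views: dict[str, np.ndarray]
    mirna_ids: list[str]
    disease_ids: list[str]
    train_pair_set: set


# ---------------------------------------------------------------------------
# training

def _views_dict(vs: SimilarityViewSet) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in vs.views.items()}


def _masked_views(views: dict[str, np.ndarray], mask_cfg: MaskConfig,
                  seed: int) -> dict[str, np.ndarray]:
    out = {}
    for i, (name, A) in enumerate(sorted(views.items())):
        out[name] = mask_graph(A, mask_cfg, seed=seed + 7919 * i).A_mask
    return out


def train(ds: AssociationDataset, m_sims: SimilarityViewSet,
          d_sims: SimilarityViewSet, cfg: ModelConfig,
          train_pairs: np.ndarray, train_labels: np.ndarray,
          forbidden_pairs: np.ndarray | None = None) -> TrainedModel:
    """Train the model on the given labelled pairs.

    ``forbidden_pairs`` (the held-out set) is asserted to contribute neither
    hypergraph edges nor loss terms; training positives are the positive
    train pairs only.
    """
    train_pairs = np.asarray(train_pairs, dtype=int)
    train_labels = np.asarray(train_labels, dtype=float)
    train_set = {(int(i), int(j)) for i, j in train_pairs}
    pos_pairs = train_pairs[train_labels == 1]
    pos_set = {(int(i), int(j)) for i, j in pos_pairs}
    if forbidden_pairs is not None:
        forb = {(int(i), int(j)) for i, j in np.asarray(forbidden_pairs, int)}
        leak = forb & train_set
        if leak:
            raise ValueError(f"held-out pairs appear in the training set: {sorted(leak)[:5]}")
    A_md = np.zeros((ds.km, ds.kd))
    for i, j in pos_set:
        A_md[i, j] = 1.0
    m_views = _views_dict(m_sims)
    d_views = _views_dict(d_sims)

    ss = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    drop_rng = np.random.default_rng(ss.spawn(1)[0])
    mask_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.epochs + 1)

    model = HGTModel(cfg, ds.km, ds.kd, sorted(m_views), sorted(d_views), init_rng)
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    losses: list[float] = []
    use_mask = cfg.ablation != "HGT-A"
    fixed_mv = fixed_dv = None
    if use_mask and cfg.fixed_mask:
        fixed_mv = _masked_views(m_views, cfg.mask, int(mask_seeds[0]) % 2**31)
        fixed_dv = _masked_views(d_views, cfg.mask, int(mask_seeds[0] + 1) % 2**31)

    for epoch in range(cfg.epochs):
        if not use_mask:
            mv, dv = m_views, d_views
        elif cfg.fixed_mask:
            mv, dv = fixed_mv, fixed_dv
        else:
            s = int(mask_seeds[epoch + 1]) % 2**31
            mv = _masked_views(m_views, cfg.mask, s)
            dv = _masked_views(d_views, cfg.mask, s + 104729)
        scores = model.forward(mv, dv, A_md, train_pairs, training=True,
                               rng=drop_rng)
        loss = dce_loss_t(train_labels, scores, cfg.loss)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite loss {val} at epoch {epoch}; trajectory so far: "
                f"{losses[-5:]}")
        losses.append(val)
        opt.zero_grad()
        loss.backward()
        opt.step()

    return TrainedModel(model, cfg, losses, A_md, m_views, d_views,
                        list(ds.mirna_ids), list(ds.disease_ids), train_set)


def predict_scores(state: TrainedModel, pairs: np.ndarray) -> np.ndarray:
    """Deterministic scores for arbitrary pairs (unmasked views, no dropout)."""
    pairs = np.asarray(pairs, dtype=int)
    with set_grad_enabled(False):
        scores = state.model.forward(state.m_views, state.d_views, state.A_md,
                                     pairs, training=False)
    return scores.data


# ---------------------------------------------------------------------------
# evaluation

def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> dict:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a single-class label vector")
    pred = (scores >= threshold).astype(int)
    return {
        "acc": float(accuracy_score(labels, pred)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "precision": float(precision_score(labels, pred, zero_division=0)),
        "auc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
    }


def evaluate(state: TrainedModel, pairs: np.ndarray, labels: np.ndarray) -> dict:
    """Score held-out pairs and compute threshold and ranking metrics.

    Raises if any evaluated pair contributed to training.
    """
    pairs = np.asarray(pairs, dtype=int)
    seen = {(int(i), int(j)) for i, j in pairs} & state.train_pair_set
    if seen:
        raise ValueError(f"evaluation pairs seen during training: {sorted(seen)[:5]}")
    return compute_metrics(labels, predict_scores(state, pairs))


def cross_validate(ds: AssociationDataset, m_sims: SimilarityViewSet,
                   d_sims: SimilarityViewSet, cfg: ModelConfig,
                   split: SplitSpec) -> EvalReport:
    """Stratified K-fold CV over the training pairs of ``split``."""
    fold_metrics = []
    for f, val_idx in enumerate(split.folds):
        mask = np.zeros(len(split.train_pairs), dtype=bool)
        mask[val_idx] = True
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.seed = int(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(f,)).generate_state(1)[0] % 2**31)
        state = train(ds, m_sims, d_sims, fold_cfg,
                      split.train_pairs[~mask], split.train_labels[~mask],
                      forbidden_pairs=split.train_pairs[mask])
        fold_metrics.append(evaluate(state, split.train_pairs[mask],
                                     split.train_labels[mask]))
    return EvalReport.from_folds(fold_metrics)


def rank_candidates(state: TrainedModel, disease_id: str, top_n: int = 20,
                    exclude_train: bool = True) -> list[tuple[str, float]]:
    """miRNAs ranked by predicted association score with one disease.

    Descending by score, ties broken by miRNA id; training positives are
    excluded by default.
    """
    if disease_id not in state.disease_ids:
        raise KeyError(f"unknown disease: {disease_id}")
    j = state.disease_ids.index(disease_id)
    cand = [i for i in range(len(state.mirna_ids))
            if not (exclude_train and (i, j) in state.train_pair_set
                    and state.A_md[i, j] == 1.0)]
    pairs = np.array([[i, j] for i in cand], dtype=int)
    scores = predict_scores(state, pairs)
    ranked = sorted(zip((state.mirna_ids[i] for i in cand), scores),
                    key=lambda t: (-t[1], t[0]))
    return [(m, float(s)) for m, s in ranked[:top_n]]
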