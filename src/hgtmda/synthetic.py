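"""Synthetic benchmark generator with planted low-rank association structure.

Emulates the statistical shape of curated miRNA-disease data: a sparse 0/1
bipartite matrix driven by a small number of latent factors (associations in
this literature are approximately low rank), plus three noisy-but-consistent
similarity views per entity type, carrying redundant signal so the multi-view
attention fusion and masking stages are genuinely exercised.

Construction: nonnegative factors U (km x rank) and V (kd x rank) are drawn,
A = 1 where U V^T exceeds its 80th percentile (about 20% positive density),
then cells are flipped independently at ``noise_flip_rate``. Each similarity
view is the cosine similarity of the factors under an independent Gaussian
perturbation (sd ``sim_noise_sd``), symmetrised, clipped to [0,1], unit
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationDataset
from .similarity import DISEASE_VIEWS, MIRNA_VIEWS, SimilarityViewSet

__all__ = ["SyntheticSpec", "generate"]

DENSITY_QUANTILE = 0.80  # A=1 above this quantile of the latent scores


@dataclass
class SyntheticSpec:
    km: int = 100
    kd: int = 60
    rank: int = 5
    noise_flip_rate: float = 0.05
    sim_noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self):
        if self.rank >= min(self.km, self.kd):
            raise ValueError("rank must be < min(km, kd)")
        if not (0.0 <= self.noise_flip_rate < 1.0):
            raise ValueError("noise_flip_rate must be in [0,1)")
        if self.sim_noise_sd < 0:
            raise ValueError("sim_noise_sd must be >= 0")


def _noisy_cosine_views(F: np.ndarray, names, sd: float,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    views = {}
    for name in names:
        Fn = F + rng.normal(0.0, sd, size=F.shape) if sd > 0 else F.copy()
        norms = np.linalg.norm(Fn, axis=1)
        norms[norms == 0] = 1.0
        C = (Fn / norms[:, None]) @ (Fn / norms[:, None]).T
        C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(C, 1.0)
        views[name] = C
    return views


def generate(spec: SyntheticSpec) -> tuple[AssociationDataset, SimilarityViewSet,
                                           SimilarityViewSet, dict[str, np.ndarray]]:
    """Generate (dataset, miRNA views, disease views, ground-truth factors)."""
    rng = np.random.default_rng(spec.seed)
    U = np.abs(rng.normal(size=(spec.km, spec.rank)))
    V = np.abs(rng.normal(size=(spec.kd, spec.rank)))
    score = U @ V.T
    thresh = np.quantile(score, DENSITY_QUANTILE)
    A = (score > thresh).astype(np.int8)
    if spec.noise_flip_rate > 0:
        flips = rng.random(A.shape) < spec.noise_flip_rate
        A = np.where(flips, 1 - A, A)
    if A.sum() == 0:
        raise ValueError("degenerate all-zero association matrix; lower the "
                         "density quantile or increase rank")
    mirna_ids = [f"mir-{i:04d}" for i in range(spec.km)]
    disease_ids = [f"disease-{j:04d}" for j in range(spec.kd)]
    ds = AssociationDataset(mirna_ids, disease_ids, A)
    m_views = SimilarityViewSet(
        "miRNA", _noisy_cosine_views(U, MIRNA_VIEWS, spec.sim_noise_sd, rng),
        mirna_ids)
    d_views = SimilarityViewSet(
        "disease", _noisy_cosine_views(V, DISEASE_VIEWS, spec.sim_noise_sd, rng),
        disease_ids)
    return ds, m_views, d_views, {"U": U, "V": V}
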