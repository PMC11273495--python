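"""Homogeneous similarity networks for miRNAs and diseases.

Three views per entity type feed the model:

miRNA    - functional (MISIM best-match average over associated diseases),
           sequence (normalised global alignment), GIP kernel.
disease  - semantic (Wang DAG measure), target-gene (Jaccard), GIP kernel.

All views are symmetric matrices in [0,1] with unit diagonal. Each measure is
implemented in its standard literature form and is pluggable: any view may be
replaced by a precomputed matrix loaded from file.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "SimilarityViewSet",
    "gip_kernel_similarity",
    "disease_semantic_similarity",
    "mirna_functional_similarity",
    "mirna_sequence_similarity",
    "disease_target_similarity",
]

MIRNA_VIEWS = ("functional", "sequence", "gip")
DISEASE_VIEWS = ("semantic", "target", "gip")


@dataclass
class SimilarityViewSet:
    """Named square similarity views over one entity type."""

    entity_kind: str  # "miRNA" | "disease"
    views: dict[str, np.ndarray]
    ids: list[str]

    def validate(self, atol: float = 1e-10) -> None:
        n = len(self.ids)
        for name, M in self.views.items():
            M = np.asarray(M)
            if M.shape != (n, n):
                raise ValueError(f"view {name}: shape {M.shape} != ({n},{n})")
            if not np.allclose(M, M.T, atol=atol):
                raise ValueError(f"view {name}: not symmetric")
            if M.min() < -atol or M.max() > 1 + atol:
                raise ValueError(f"view {name}: entries outside [0,1]")
            if not np.allclose(np.diag(M), 1.0, atol=atol):
                raise ValueError(f"view {name}: diagonal != 1")

    def matrices(self) -> list[np.ndarray]:
        order = MIRNA_VIEWS if self.entity_kind == "miRNA" else DISEASE_VIEWS
        return [self.views[k] for k in order if k in self.views]


# ---------------------------------------------------------------------------
# Gaussian interaction profile kernel

def gip_kernel_similarity(A: np.ndarray, axis: str = "rows") -> np.ndarray:
    """GIP kernel K(i,j) = exp(-gamma ||IP(i)-IP(j)||^2) over binary profiles.

    The bandwidth gamma is 1 over the mean squared profile norm
    (van Laarhoven normalisation).
    """
    A = np.asarray(A, dtype=float)
    P = A if axis == "rows" else A.T
    if P.size == 0:
        raise ValueError("degenerate association matrix")
    norms2 = (P ** 2).sum(axis=1)
    mean_norm2 = norms2.mean()
    if mean_norm2 == 0:
        raise ValueError(
            "all-zero association matrix: GIP bandwidth undefined; add "
            "pseudo-associations or skip this view")
    gamma = 1.0 / mean_norm2
    D2 = squareform(pdist(P, metric="sqeuclidean")) if P.shape[0] > 1 else np.zeros((1, 1))
    K = np.exp(-gamma * D2)
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# Wang semantic similarity on a disease DAG

def _ancestor_closure(parents: dict[str, list[str]], d: str) -> set[str]:
    seen, stack = {d}, [d]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


def _svalues(parents: dict[str, list[str]], d: str, decay: float) -> dict[str, float]:
    """Semantic contribution of each ancestor of d (Wang S-values).

    S(d)=1; S(t)=decay * max over children of t inside d's ancestor closure.
    Computed by relaxation from d upward (closure DAGs are small).
    """
    closure = _ancestor_closure(parents, d)
    S = {d: 1.0}
    frontier = [d]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in closure:
                    continue
                cand = decay * S[t]
                if cand > S.get(p, 0.0):
                    S[p] = cand
                    nxt.append(p)
        frontier = nxt
    return S


def disease_semantic_similarity(dag: list[tuple[str, str]], decay: float = 0.5,
                                ids: list[str] | None = None) -> np.ndarray:
    """Wang semantic similarity over a child->parent disease DAG.

    sim(a,b) = sum over shared ancestors of (Sa+Sb) / (sum Sa + sum Sb).
    Diseases absent from the DAG get 0 off-diagonal, 1 on the diagonal.
    """
    parents: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for child, parent in dag:
        parents.setdefault(child, []).append(parent)
        nodes.update((child, parent))
    try:
        TopologicalSorter({c: set(ps) for c, ps in parents.items()}).prepare()
    except CycleError as e:
        raise ValueError(f"disease DAG contains a cycle: {e.args[1]}") from e
    if ids is None:
        ids = sorted(nodes)
    sv = {d: _svalues(parents, d, decay) if d in nodes else {d: 1.0} for d in ids}
    totals = {d: sum(sv[d].values()) for d in ids}
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            shared = sv[a].keys() & sv[b].keys()
            if shared:
                num = sum(sv[a][t] + sv[b][t] for t in shared)
                S[i, j] = S[j, i] = num / (totals[a] + totals[b])
    return S


# ---------------------------------------------------------------------------
# MISIM miRNA functional similarity

def mirna_functional_similarity(disease_sem: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Best-match average of disease semantic similarities (MISIM).

    sim(m1,m2) = (sum_{d in D1} max_{d' in D2} S + sum_{d in D2} max_{d' in D1} S)
                 / (|D1| + |D2|).
    miRNAs with no associated disease get 0 off-diagonal, 1 on the diagonal.
    """
    S = np.asarray(disease_sem, dtype=float)
    A = np.asarray(A)
    if S.shape[0] != A.shape[1]:
        raise ValueError(
            f"disease similarity is {S.shape[0]}x{S.shape[0]} but association "
            f"matrix has {A.shape[1]} diseases")
    km = A.shape[0]
    dsets = [np.nonzero(A[i])[0] for i in range(km)]
    F = np.eye(km)
    for i in range(km):
        Di = dsets[i]
        if len(Di) == 0:
            continue
        for j in range(i + 1, km):
            Dj = dsets[j]
            if len(Dj) == 0:
                continue
            block = S[np.ix_(Di, Dj)]
            num = block.max(axis=1).sum() + block.max(axis=0).sum()
            F[i, j] = F[j, i] = num / (len(Di) + len(Dj))
    return np.clip(F, 0.0, 1.0)


# ---------------------------------------------------------------------------
# sequence similarity

def mirna_sequence_similarity(seqs: dict[str, str], match: float = 1.0,
                              mismatch: float = 0.0, gap: float = 0.0,
                              ids: list[str] | None = None) -> np.ndarray:
    """Global pairwise alignment score normalised by self-alignment.

    sim(i,j) = score(i,j) / sqrt(score(i,i) * score(j,j)) under a configurable
    match/mismatch/gap scheme (defaults 1/0/0).
    """
    from Bio import Align

    if ids is None:
        ids = sorted(seqs)
    alphabet = set("ACGUT")
    for name in ids:
        s = seqs[name].upper()
        if not s:
            raise ValueError(f"empty sequence for {name}")
        bad = set(s) - alphabet
        if bad:
            raise ValueError(f"invalid character(s) {sorted(bad)} in sequence {name}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # U and T treated as the same base
    norm = {name: seqs[name].upper().replace("T", "U") for name in ids}
    n = len(ids)
    self_scores = np.array([aligner.score(norm[i], norm[i]) for i in ids])
    if np.any(self_scores <= 0):
        raise ValueError("self-alignment score must be positive (check match score)")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sc = aligner.score(norm[ids[i]], norm[ids[j]])
            S[i, j] = S[j, i] = sc / np.sqrt(self_scores[i] * self_scores[j])
    return np.clip(S, 0.0, 1.0)


# ---------------------------------------------------------------------------
# target-gene similarity

def disease_target_similarity(targets: dict[str, set[str]],
                              ids: list[str] | None = None) -> np.ndarray:
    """Jaccard index over gene sets; both-empty pairs score 0, diagonal 1."""
    if ids is None:
        ids = sorted(targets)
    sets = [frozenset(targets.get(d, ())) for d in ids]
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[i], sets[j]
            union = len(a | b)
            S[i, j] = S[j, i] = (len(a & b) / union) if union else 0.0
    return S
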