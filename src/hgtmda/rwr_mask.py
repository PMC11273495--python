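"""Restart-based random-walk association masking.

Training-time augmentation on the homogeneous similarity networks: start
nodes are drawn by independent Bernoulli(p) trials, a random walk with
restart probability c of length k is run from each, and the adjacency entries
covered by the union of path outer products are masked.

Two masking modes exist because keeping versus removing the covered entries
are both defensible readings of the elementwise-product formulation:
``complement`` (default) zeroes the covered entries — masking removes
associations; ``literal`` keeps only the covered entries. The two modes are
exact complements: literal(A) + complement(A) = A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskConfig",
    "MaskedGraph",
    "sample_start_nodes",
    "rwr_transition_matrix",
    "extract_path",
    "path_mask_vector",
    "apply_association_mask",
    "mask_graph",
]


@dataclass
class MaskConfig:
    """Masking hyperparameters.

    p: Bernoulli start-node sampling rate; c: restart probability;
    k: walk length in steps; mode: complement | literal.
    """

    p: float = 0.3
    c: float = 0.6
    k: int = 8
    seed: int = 0
    mode: str = "complement"
    edge_threshold: float = 0.0  # weights <= threshold excluded from the walk

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0,1]")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must be in [0,1]")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.mode not in ("complement", "literal"):
            raise ValueError("mode must be 'complement' or 'literal'")


@dataclass
class MaskedGraph:
    A_mask: np.ndarray
    masked_entries: set[tuple[int, int]] = field(default_factory=set)
    paths: dict[int, list[int]] = field(default_factory=dict)
    start_nodes: list[int] = field(default_factory=list)


def sample_start_nodes(n: int, p: float, seed: int) -> list[int]:
    """Independent Bernoulli(p) inclusion of each of the n nodes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    rng = np.random.default_rng(seed)
    return list(np.nonzero(rng.random(n) < p)[0])


def rwr_transition_matrix(A: np.ndarray, c: float) -> np.ndarray:
    """P = (1-c) D^-1 A + c I, with P[i,i]=1 for isolated nodes."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    deg = A.sum(axis=1)
    P = np.zeros_like(A)
    nz = deg > 0
    P[nz] = (1.0 - c) * A[nz] / deg[nz, None]
    P[np.arange(len(A)), np.arange(len(A))] += c
    iso = ~nz
    P[iso] = 0.0
    P[np.nonzero(iso)[0], np.nonzero(iso)[0]] = 1.0
    return P


def extract_path(P: np.ndarray, v: int, k: int, seed: int, c: float = 0.0) -> list[int]:
    """Length-(k+1) walk from v: restart to v with probability c, else a step
    drawn from the current node's row of P. Restart events emit v.

    P is the neighbour transition matrix (rows stochastic); restart is applied
    on top of it so the walker returns to the *start* node, not merely stays
    in place.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    path = [int(v)]
    cur = int(v)
    for _ in range(k):
        if c > 0.0 and rng.random() < c:
            cur = int(v)
        else:
            row = P[cur]
            s = row.sum()
            if s <= 0:
                raise ValueError(f"node {cur}: all-zero transition row")
            cur = int(rng.choice(n, p=row / s))
        path.append(cur)
    return path


def path_mask_vector(path: list[int], n: int) -> np.ndarray:
    """Binary membership vector: entry j is 1 iff node j occurs in the path."""
    m = np.zeros(n, dtype=np.int8)
    idx = np.asarray(path, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("path entry out of range")
    m[idx] = 1
    return m


def apply_association_mask(A: np.ndarray, mask_vectors: list[np.ndarray],
                           mode: str = "complement") -> MaskedGraph:
    """Apply the union of outer products m m^T as an association mask.

    literal: keep only covered entries (elementwise product with the union);
    complement: zero covered entries, keep the rest. Coverage is symmetrised
    so undirected graphs stay undirected.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if mode not in ("complement", "literal"):
        raise ValueError("mode must be 'complement' or 'literal'")
    if not mask_vectors:
        return MaskedGraph(A.copy(), set())
    cover = np.zeros((n, n), dtype=bool)
    for m in mask_vectors:
        m = np.asarray(m).astype(bool)
        if m.shape[0] != n:
            raise ValueError("mask vector length mismatch")
        cover |= np.outer(m, m)
    cover |= cover.T
    if mode == "literal":
        A_mask = np.where(cover, A, 0.0)
        changed = (~cover) & (A != 0)
    else:
        A_mask = np.where(cover, 0.0, A)
        changed = cover & (A != 0)
    masked = set(zip(*np.nonzero(changed)))
    return MaskedGraph(A_mask, {(int(i), int(j)) for i, j in masked})


def mask_graph(A: np.ndarray, cfg: MaskConfig, seed: int | None = None) -> MaskedGraph:
    """Full masking pipeline on one similarity network.

    Samples start nodes, runs one restart walk per start node on the
    thresholded graph, builds membership vectors and applies the mask.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    seed = cfg.seed if seed is None else seed
    starts = sample_start_nodes(n, cfg.p, seed)
    W = np.where(A > cfg.edge_threshold, A, 0.0)
    P = rwr_transition_matrix(W, 0.0)  # neighbour steps; restart applied in walk
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    child_seeds = ss.generate_state(max(len(starts), 1))
    paths = {int(v): extract_path(P, v, cfg.k, int(child_seeds[i]), c=cfg.c)
             for i, v in enumerate(starts)}
    vectors = [path_mask_vector(p, n) for p in paths.values()]
    out = apply_association_mask(A, vectors, cfg.mode)
    out.paths = paths
    out.start_nodes = starts
    return out
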