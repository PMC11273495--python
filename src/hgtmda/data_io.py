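"""Association data handling: edge lists, balanced sampling, splits, matrices.

The association data is a bipartite 0/1 matrix between miRNAs (rows) and
diseases (columns). Known associations are positives; an equal number of
negatives is drawn uniformly from the zero cells to form a balanced labelled
dataset, which is then split 8:2 into train/test with stratified K folds over
the training pairs for cross-validation.

Identifier normalisation: miRNA ids are lowercased and stripped; disease names
are matched case-insensitively (canonicalised to lowercase).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "AssociationDataset",
    "SplitSpec",
    "load_associations",
    "write_associations",
    "sample_negatives",
    "make_splits",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "read_dag_edges",
    "read_target_sets",
]

Pair = tuple[int, int]


def _norm_mirna(s: str) -> str:
    return s.strip().lower()


def _norm_disease(s: str) -> str:
    return s.strip().lower()


@dataclass
class AssociationDataset:
    """Bipartite miRNA-disease association matrix with labelled pair lists."""

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray  # km x kd binary
    positive_pairs: list[Pair] = field(default_factory=list)
    negative_pairs: list[Pair] = field(default_factory=list)

    def __post_init__(self):
        self.A = np.asarray(self.A)
        km, kd = self.A.shape
        if km != len(self.mirna_ids) or kd != len(self.disease_ids):
            raise ValueError("matrix shape does not match id lists")
        if not self.positive_pairs:
            self.positive_pairs = [tuple(p) for p in zip(*np.nonzero(self.A))]

    @property
    def km(self) -> int:
        return len(self.mirna_ids)

    @property
    def kd(self) -> int:
        return len(self.disease_ids)

    def validate(self) -> None:
        pos = set(self.positive_pairs)
        ones = set(zip(*np.nonzero(self.A)))
        if pos != ones:
            raise ValueError("positive_pairs inconsistent with A")
        if pos & set(self.negative_pairs):
            raise ValueError("negative pair overlaps a positive pair")
        for i, j in self.negative_pairs:
            if not (0 <= i < self.km and 0 <= j < self.kd):
                raise ValueError(f"pair ({i},{j}) out of range")

    def labelled_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All balanced pairs as an (n,2) index array plus 0/1 labels."""
        pairs = np.array(list(self.positive_pairs) + list(self.negative_pairs),
                         dtype=np.int64)
        labels = np.concatenate([
            np.ones(len(self.positive_pairs)),
            np.zeros(len(self.negative_pairs)),
        ])
        return pairs, labels


@dataclass
class SplitSpec:
    """Train/test split plus K disjoint validation folds over the train set.

    ``train_pairs`` / ``test_pairs`` are (n,2) integer index arrays with
    matching 0/1 label vectors; ``folds`` holds index sets into the train
    arrays. Identical seed (and inputs) yields an identical SplitSpec.
    """

    train_pairs: np.ndarray
    train_labels: np.ndarray
    test_pairs: np.ndarray
    test_labels: np.ndarray
    folds: list[np.ndarray]
    seed: int


# ---------------------------------------------------------------------------
# edge lists

def _read_table(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty association file: {path}")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     skip_blank_lines=True)
    # optional header: first row made of recognisable column names
    header_words = {"mirna", "mirna_id", "mir", "disease", "disease_id",
                    "disease_name", "source", "target", "label"}
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if set(first) & header_words:
        df = df.iloc[1:].reset_index(drop=True)
    return df


def load_associations(path, mirna_universe=None, disease_universe=None) -> AssociationDataset:
    """Read a 2+ column miRNA/disease edge list into an AssociationDataset.

    Duplicated pairs collapse to one; universes default to the sorted distinct
    ids observed in the file.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need >= 2 columns (miRNA id, disease id)")
    pairs: list[tuple[str, str]] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        m, d = row[0], row[1]
        if pd.isna(m) or pd.isna(d) or not str(m).strip() or not str(d).strip():
            raise ValueError(f"{path}: malformed row at line {lineno}")
        pairs.append((_norm_mirna(str(m)), _norm_disease(str(d))))
    if mirna_universe is None:
        mirna_universe = sorted({m for m, _ in pairs})
    else:
        mirna_universe = [_norm_mirna(m) for m in mirna_universe]
    if disease_universe is None:
        disease_universe = sorted({d for _, d in pairs})
    else:
        disease_universe = [_norm_disease(d) for d in disease_universe]
    mi = {m: i for i, m in enumerate(mirna_universe)}
    di = {d: j for j, d in enumerate(disease_universe)}
    A = np.zeros((len(mirna_universe), len(disease_universe)), dtype=np.int8)
    for m, d in pairs:
        if m not in mi:
            raise ValueError(f"miRNA {m!r} not in provided universe")
        if d not in di:
            raise ValueError(f"disease {d!r} not in provided universe")
        A[mi[m], di[d]] = 1
    return AssociationDataset(mirna_universe, disease_universe, A)


def write_associations(ds: AssociationDataset, path) -> None:
    """Write the canonical (sorted, deduplicated) edge list as TSV."""
    rows = sorted((ds.mirna_ids[i], ds.disease_ids[j]) for i, j in ds.positive_pairs)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# balancing and splitting

def sample_negatives(ds: AssociationDataset, seed: int) -> AssociationDataset:
    """Draw |positives| negative pairs uniformly from the zero cells."""
    zeros = np.argwhere(ds.A == 0)
    n_pos = len(ds.positive_pairs)
    if len(zeros) < n_pos:
        raise ValueError(
            f"cannot balance: {len(zeros)} zero cells < {n_pos} positives")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zeros), size=n_pos, replace=False)
    negatives = [tuple(zeros[k]) for k in sorted(pick)]
    return AssociationDataset(ds.mirna_ids, ds.disease_ids, ds.A,
                              list(ds.positive_pairs), negatives)


def make_splits(ds: AssociationDataset, test_fraction: float = 0.2,
                k_folds: int = 5, seed: int = 0) -> SplitSpec:
    """Stratified train/test split and K stratified folds over the train set."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0,1)")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    pairs, labels = ds.labelled_pairs()
    if len(pairs) < k_folds:
        raise ValueError("fewer pairs than folds")
    idx = np.arange(len(pairs))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=labels)
    tr, te = np.sort(tr), np.sort(te)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = [np.sort(val) for _, val in skf.split(tr, labels[tr])]
    return SplitSpec(pairs[tr], labels[tr], pairs[te], labels[te], folds, seed)


# ---------------------------------------------------------------------------
# matrices and raw similarity inputs

def write_matrix(M: np.ndarray, ids, path) -> None:
    """Square matrix as TSV with an id header row and id index column."""
    pd.DataFrame(np.asarray(M), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix not square")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_fasta(path) -> dict[str, str]:
    """miRNA sequences keyed by normalised id."""
    from Bio import SeqIO

    return {_norm_mirna(rec.id): str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_dag_edges(path) -> list[tuple[str, str]]:
    """Disease ontology DAG as (child, parent) edges from a 2-column TSV."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (child, parent)")
    return [(_norm_disease(str(c)), _norm_disease(str(p)))
            for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_target_sets(path) -> dict[str, set[str]]:
    """Entity -> gene set map from a 2-column TSV (entity, gene)."""
    df = _read_table(path)
    out: dict[str, set[str]] = {}
    for e, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(e).strip().lower(), set()).add(str(g).strip())
    return out
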