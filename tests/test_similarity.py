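import numpy as np
import pytest

from hgtmda import similarity as sim


# ---------------------------------------------------------------------------
# independent oracles

def gip_oracle(A, axis):
    P = A if axis == "rows" else A.T
    gamma = 1.0 / np.mean([np.dot(p, p) for p in P])
    n = P.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = P[i] - P[j]
            K[i, j] = np.exp(-gamma * np.dot(d, d))
    return K


def wang_oracle(parent_map, decay, a, b):
    """Path-enumeration evaluation of the Wang measure (independent of the
    relaxation used in the implementation)."""
    def contributions(d):
        best = {}

        def walk(node, w):
            if w > best.get(node, 0.0):
                best[node] = w
                for p in parent_map.get(node, ()):
                    walk(p, w * decay)

        walk(d, 1.0)
        return best

    Sa, Sb = contributions(a), contributions(b)
    shared = Sa.keys() & Sb.keys()
    if not shared:
        return 0.0
    return sum(Sa[t] + Sb[t] for t in shared) / (sum(Sa.values()) + sum(Sb.values()))


def random_dag(rng, n):
    """Random DAG on n nodes; edges point child(i) -> parent(j) with j < i."""
    edges = []
    for i in range(1, n):
        for j in range(i):
            if rng.random() < 0.3:
                edges.append((f"n{i}", f"n{j}"))
    return edges


# ---------------------------------------------------------------------------
# GIP kernel

class TestGIP:
    def test_identity_profiles_hand_value(self):
        # profiles (1,0) and (0,1): gamma = 1, distance^2 = 2
        K = sim.gip_kernel_similarity(np.eye(2), axis="rows")
        assert np.allclose(np.diag(K), 1.0)
        assert np.isclose(K[0, 1], np.exp(-2.0))

    def test_identical_profiles_score_one(self):
        A = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        K = sim.gip_kernel_similarity(A, axis="rows")
        assert np.isclose(K[0, 1], 1.0)

    @pytest.mark.parametrize("axis", ["rows", "columns"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, axis, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((10, 8)) < 0.4).astype(float)
        if A.sum() == 0:
            A[0, 0] = 1
        K = sim.gip_kernel_similarity(A, axis=axis)
        assert np.allclose(K, gip_oracle(A, axis), atol=1e-12)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="bandwidth"):
            sim.gip_kernel_similarity(np.zeros((4, 3)), axis="rows")


# ---------------------------------------------------------------------------
# Wang semantic similarity

class TestSemantic:
    def test_self_similarity_one(self):
        S = sim.disease_semantic_similarity([("a", "root")], ids=["a", "root"])
        assert np.allclose(np.diag(S), 1.0)

    def test_disjoint_dags_score_zero(self):
        S = sim.disease_semantic_similarity([("a", "r1"), ("b", "r2")],
                                            ids=["a", "b"])
        assert S[0, 1] == 0.0

    def test_three_node_chain_hand_value(self):
        # root -> a -> b: S_b = {b:1, a:.5, root:.25}; S_a = {a:1, root:.5}
        S = sim.disease_semantic_similarity([("a", "root"), ("b", "a")],
                                            decay=0.5, ids=["a", "b"])
        assert np.isclose(S[0, 1], (0.5 + 1 + 0.25 + 0.5) / (1.75 + 1.5))

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            sim.disease_semantic_similarity([("a", "b"), ("b", "a")])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        edges = random_dag(rng, n)
        ids = [f"n{i}" for i in range(n)]
        parent_map = {}
        for c, p in edges:
            parent_map.setdefault(c, []).append(p)
        S = sim.disease_semantic_similarity(edges, decay=0.5, ids=ids)
        for _ in range(10):
            i, j = rng.integers(0, n, 2)
            expected = 1.0 if i == j else wang_oracle(parent_map, 0.5,
                                                      ids[i], ids[j])
            assert np.isclose(S[i, j], expected), (i, j)


# ---------------------------------------------------------------------------
# MISIM functional similarity

class TestFunctional:
    def test_identical_disease_sets(self):
        A = np.array([[1, 1, 0], [1, 1, 0]])
        S = np.eye(3)
        F = sim.mirna_functional_similarity(S, A)
        assert np.isclose(F[0, 1], 1.0)

    def test_unrelated_disease_sets(self):
        A = np.array([[1, 0], [0, 1]])
        F = sim.mirna_functional_similarity(np.eye(2), A)
        assert F[0, 1] == 0.0

    def test_single_disease_pair_hand_value(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        A = np.array([[1, 0], [0, 1]])
        F = sim.mirna_functional_similarity(S, A)
        assert np.isclose(F[0, 1], 0.6)

    def test_orphan_mirna_row(self):
        A = np.array([[1, 0], [0, 0]])
        F = sim.mirna_functional_similarity(np.eye(2), A)
        assert F[1, 1] == 1.0 and F[0, 1] == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sim.mirna_functional_similarity(np.eye(3), np.ones((2, 2)))


# ---------------------------------------------------------------------------
# sequence similarity

class TestSequence:
    def test_identical_sequences(self):
        S = sim.mirna_sequence_similarity({"a": "ACGU", "b": "ACGU"})
        assert np.isclose(S[0, 1], 1.0)

    def test_fully_mismatched(self):
        S = sim.mirna_sequence_similarity({"a": "AAAA", "b": "CCCC"})
        assert np.isclose(S[0, 1], 0.0)

    def test_half_matching_hand_alignment(self):
        S = sim.mirna_sequence_similarity({"a": "AACC", "b": "AAGG"})
        assert np.isclose(S[0, 1], 0.5)

    def test_t_u_equivalence(self):
        S = sim.mirna_sequence_similarity({"a": "ACGT", "b": "ACGU"})
        assert np.isclose(S[0, 1], 1.0)

    def test_invalid_character_names_sequence(self):
        with pytest.raises(ValueError, match="xx"):
            sim.mirna_sequence_similarity({"xx": "ACGN"})


# ---------------------------------------------------------------------------
# target similarity

class TestTarget:
    @pytest.mark.parametrize("a,b,expected", [
        ({"g1", "g2"}, {"g1", "g2"}, 1.0),
        ({"g1"}, {"g2"}, 0.0),
        ({"g1", "g2"}, {"g2", "g3"}, 1 / 3),
        (set(), set(), 0.0),
    ])
    def test_jaccard_values(self, a, b, expected):
        S = sim.disease_target_similarity({"d1": a, "d2": b}, ids=["d1", "d2"])
        assert np.isclose(S[0, 1], expected)
        assert np.allclose(np.diag(S), 1.0)


# ---------------------------------------------------------------------------
# cross-view invariants

def test_all_views_symmetric_unit_diagonal_in_range(default_fixture, rng):
    ds, m_views, d_views, _ = default_fixture
    m_views.validate()
    d_views.validate()
    # computed views obey the same contract
    A = (rng.random((12, 9)) < 0.3).astype(float)
    A[0, 0] = 1
    views = {
        "gip_rows": sim.gip_kernel_similarity(A, "rows"),
        "gip_cols": sim.gip_kernel_similarity(A, "columns"),
        "target": sim.disease_target_similarity(
            {f"d{i}": {f"g{rng.integers(5)}"} for i in range(6)}),
        "functional": sim.mirna_functional_similarity(np.eye(9), A),
    }
    for name, M in views.items():
        assert np.allclose(M, M.T, atol=1e-10), name
        assert np.allclose(np.diag(M), 1.0), name
        assert M.min() >= 0 and M.max() <= 1 + 1e-12, name
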