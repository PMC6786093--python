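import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdcap import (
    BipartiteNetwork,
    DiseaseOntology,
    NoOntologyError,
    SimilarityMatrix,
    disease_similarity,
    functional_similarity,
    gip_kernel,
    hub_promoted_index,
    semantic_profile,
    semantic_similarity_matrix,
)
from conftest import random_network


class TestSemanticProfile:
    def test_chain(self, chain_ontology):
        p = semantic_profile(chain_ontology, "heart attack", delta=0.5)
        assert p.contributions == {"C01.01": 1.0, "C01": 0.5}
        assert p.total_value == 1.5

    def test_root_term(self, chain_ontology):
        p = semantic_profile(chain_ontology, "root disease", delta=0.5)
        assert p.contributions == {"C01": 1.0} and p.total_value == 1.0

    def test_diamond_takes_max_over_paths(self):
        # the ancestor A01 is 2 hops up one tree number and 3 hops up the other
        ont = DiseaseOntology({"dual": {"A01.01.01", "A01.02.03.04"}})
        p = semantic_profile(ont, "dual", delta=0.5)
        assert p.contributions["A01"] == pytest.approx(0.25)

    def test_contributions_non_increasing_upward(self, chain_ontology):
        p = semantic_profile(chain_ontology, "heart attack")
        for term, val in p.contributions.items():
            parent = DiseaseOntology.parent(term)
            if parent in p.contributions:
                assert p.contributions[parent] <= val

    def test_unresolvable_raises(self, chain_ontology):
        with pytest.raises(NoOntologyError):
            semantic_profile(chain_ontology, "no such disease")


class TestDiseaseSimilarity:
    def test_self_similarity(self, chain_ontology):
        p = semantic_profile(chain_ontology, "heart attack")
        assert disease_similarity(p, p) == pytest.approx(1.0)

    def test_siblings(self, chain_ontology):
        p1 = semantic_profile(chain_ontology, "heart attack", 0.5)
        p2 = semantic_profile(chain_ontology, "stroke", 0.5)
        assert disease_similarity(p1, p2) == pytest.approx(1 / 3)

    def test_disjoint_trees(self, chain_ontology):
        p1 = semantic_profile(chain_ontology, "heart attack")
        p2 = semantic_profile(chain_ontology, "far disease")
        assert disease_similarity(p1, p2) == 0.0

    def test_matrix_marks_unresolved_as_nan(self, chain_ontology):
        sm = semantic_similarity_matrix(chain_ontology, ["heart attack", "unknown x"])
        assert sm.values[0, 0] == 1.0
        assert np.isnan(sm.values[1, 1]) and np.isnan(sm.values[0, 1])


def _net(adj, mirnas=None, diseases=None):
    adj = np.asarray(adj, dtype=float)
    m, d = adj.shape
    return BipartiteNetwork(
        mirnas or [f"hsa-mir-{i}" for i in range(m)],
        diseases or [f"d{j}" for j in range(d)],
        adj,
    )


class TestFunctionalSimilarity:
    def sim(self, values, labels):
        return SimilarityMatrix(labels, np.array(values, dtype=float), "semantic")

    def test_identical_disease_sets(self):
        net = _net([[1, 1], [1, 1]])
        ds = self.sim([[1, 1 / 3], [1 / 3, 1]], net.diseases)
        fs = functional_similarity(net, ds)
        assert fs.values[0, 1] == pytest.approx(1.0)

    def test_single_disease_pair(self):
        net = _net([[1, 0], [0, 1]])
        ds = self.sim([[1, 1 / 3], [1 / 3, 1]], net.diseases)
        assert functional_similarity(net, ds).values[0, 1] == pytest.approx(1 / 3)

    def test_overlapping_sets_hand_value(self):
        # D1={d0,d1}, D2={d1}, sim(d0,d1)=1/3 -> (1/3 + 1 + 1) / 3 = 7/9
        net = _net([[1, 1], [0, 1]])
        ds = self.sim([[1, 1 / 3], [1 / 3, 1]], net.diseases)
        assert functional_similarity(net, ds).values[0, 1] == pytest.approx(7 / 9)

    def test_mirna_with_no_profiled_disease_is_undefined(self):
        net = _net([[1, 0], [0, 1]])
        vals = np.array([[1.0, np.nan], [np.nan, np.nan]])  # d1 unprofiled
        fs = functional_similarity(net, self.sim(vals, net.diseases))
        assert np.isnan(fs.values[1, 1]) and np.isnan(fs.values[0, 1])
        assert fs.values[0, 0] == 1.0


class TestGipKernel:
    def test_identical_profiles(self):
        net = _net([[1, 0], [1, 0], [0, 1]])
        assert gip_kernel(net, "mirna").values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_hand_value(self):
        net = _net([[1, 0], [0, 1]])
        K = gip_kernel(net, "mirna", bandwidth_scale=1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-2))

    def test_doubling_bandwidth_squares_offdiagonal(self):
        rng = np.random.default_rng(3)
        net = random_network(rng)
        K1 = gip_kernel(net, "disease", 1.0).values
        K2 = gip_kernel(net, "disease", 2.0).values
        off = ~np.eye(len(net.diseases), dtype=bool)
        assert np.allclose(K2[off], K1[off] ** 2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        net = random_network(rng)
        pm = rng.permutation(len(net.mirnas))
        pd = rng.permutation(len(net.diseases))
        permuted = BipartiteNetwork(
            [net.mirnas[i] for i in pm],
            [net.diseases[j] for j in pd],
            net.adjacency[np.ix_(pm, pd)],
        )
        K = gip_kernel(net, "mirna").values
        Kp = gip_kernel(permuted, "mirna").values
        assert np.allclose(Kp, K[np.ix_(pm, pm)], atol=1e-12)


class TestHubPromotedIndex:
    def test_equal_neighborhoods(self):
        net = _net([[1, 1, 0], [1, 1, 0]])
        assert hub_promoted_index(net, "mirna").values[0, 1] == 1.0

    def test_half_overlap(self):
        net = _net([[1, 1, 0], [0, 1, 1]])  # N(i)={a,b}, N(j)={b,c}
        assert hub_promoted_index(net, "mirna").values[0, 1] == pytest.approx(0.5)

    def test_disjoint_neighborhoods(self):
        net = _net([[1, 0], [0, 1]])
        assert hub_promoted_index(net, "mirna").values[0, 1] == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_hpi_at_least_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        A = net.adjacency
        H = hub_promoted_index(net, "mirna").values
        inter = A @ A.T
        deg = A.sum(axis=1)
        union = deg[:, None] + deg[None, :] - inter
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
        assert (H >= jac - 1e-12).all()


@pytest.mark.parametrize("seed", range(5))
def test_kernels_match_naive_double_loops(seed):
    """Vectorised GIP and HPI equal naive per-pair recomputation (<=6x6)."""
    rng = np.random.default_rng(seed)
    net = random_network(rng, n_m=5, n_d=6)
    for side, P in (("mirna", net.adjacency), ("disease", net.adjacency.T)):
        gamma = 1.0 / np.mean([(p**2).sum() for p in P])
        K = gip_kernel(net, side).values
        H = hub_promoted_index(net, side).values
        n = P.shape[0]
        for i in range(n):
            for j in range(n):
                expected = 1.0 if i == j else np.exp(-gamma * ((P[i] - P[j]) ** 2).sum())
                assert abs(K[i, j] - expected) < 1e-12
                Ni, Nj = set(np.flatnonzero(P[i])), set(np.flatnonzero(P[j]))
                if i == j:
                    hexp = 1.0
                elif not Ni or not Nj:
                    hexp = 0.0
                else:
                    hexp = len(Ni & Nj) / min(len(Ni), len(Nj))
                assert abs(H[i, j] - hexp) < 1e-12


def test_semantic_and_functional_match_naive_recomputation(planted):
    """Matrix implementations agree with direct per-pair formula evaluation."""
    _, net, _, ontology = planted
    diseases = net.diseases[:6]
    sm = semantic_similarity_matrix(ontology, diseases, 0.5)
    profiles = {d: semantic_profile(ontology, d, 0.5) for d in diseases}
    for i, a in enumerate(diseases):
        for j, b in enumerate(diseases):
            shared = profiles[a].contributions.keys() & profiles[b].contributions.keys()
            expected = sum(
                profiles[a].contributions[t] + profiles[b].contributions[t]
                for t in shared
            ) / (profiles[a].total_value + profiles[b].total_value)
            assert abs(sm.values[i, j] - expected) < 1e-12

    full_sm = semantic_similarity_matrix(ontology, net.diseases, 0.5)
    fs = functional_similarity(net, full_sm).values
    S = full_sm.values
    sets = [np.flatnonzero(net.adjacency[i]) for i in range(6)]
    for i in range(6):
        for j in range(6):
            Di, Dj = sets[i], sets[j]
            best_ij = sum(max(S[d, e] for e in Dj) for d in Di)
            best_ji = sum(max(S[d, e] for e in Di) for d in Dj)
            expected = (best_ij + best_ji) / (len(Di) + len(Dj))
            if i == j:
                expected = 1.0
            assert abs(fs[i, j] - expected) < 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_similarity_invariants_on_random_networks(seed, planted):
    """Symmetry, [0,1] range and unit self-similarity across all four kinds."""
    rng = np.random.default_rng(seed)
    net = random_network(rng, n_m=6, n_d=5)
    _, pnet, _, ontology = planted
    mats = [
        gip_kernel(net, "mirna"),
        gip_kernel(net, "disease"),
        hub_promoted_index(net, "mirna"),
        hub_promoted_index(net, "disease"),
        semantic_similarity_matrix(ontology, pnet.diseases),
        functional_similarity(pnet, semantic_similarity_matrix(ontology, pnet.diseases)),
    ]
    for m in mats:
        v = m.values
        assert np.array_equal(np.isnan(v), np.isnan(v.T))
        d = ~np.isnan(v)
        assert np.abs((v - v.T)[d & d.T]).max() < 1e-12
        assert v[d].min() >= 0 and v[d].max() <= 1
        diag = np.diag(v)
        assert np.all(diag[~np.isnan(diag)] == 1.0)


def test_similarity_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    net = random_network(rng)
    K = gip_kernel(net, "mirna")
    K.to_tsv(tmp_path / "k.tsv")
    back = SimilarityMatrix.from_tsv(tmp_path / "k.tsv", "gip")
    assert back.labels == K.labels
    assert np.allclose(back.values, K.values, atol=1e-9)
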