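import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdcap import (
    BipartiteNetwork,
    EdgeSplit,
    MdcapError,
    MDCAPConfig,
    evaluate_split,
    kfold_splits,
    repeat_evaluation,
    roc_auc,
    split_holdout,
)
from mdcap.pipeline import integrated_similarities
from conftest import random_network


@pytest.fixture
def ten_edge_net():
    rng = np.random.default_rng(42)
    while True:
        net = random_network(rng, n_m=4, n_d=5)
        if net.n_edges == 10:
            return net


class TestSplitHoldout:
    def test_sizes(self, ten_edge_net):
        split = split_holdout(ten_edge_net, 0.2, seed=0)
        assert len(split.test_edges) == 2 and len(split.train_edges) == 8
        assert set(split.train_edges) | set(split.test_edges) == set(ten_edge_net.edges())

    def test_deterministic(self, ten_edge_net):
        a = split_holdout(ten_edge_net, 0.2, seed=5)
        b = split_holdout(ten_edge_net, 0.2, seed=5)
        assert a == b

    def test_extreme_fraction_raises(self, ten_edge_net):
        with pytest.raises(MdcapError):
            split_holdout(ten_edge_net, 0.01, seed=0)
        with pytest.raises(MdcapError):
            split_holdout(ten_edge_net, 1.2, seed=0)

    def test_edge_sampling_is_uniform(self, ten_edge_net):
        """Over 1000 resamplings each edge lands in test ~200 times (binomial)."""
        counts = {e: 0 for e in ten_edge_net.edges()}
        for seed in range(1000):
            for e in split_holdout(ten_edge_net, 0.2, seed).test_edges:
                counts[e] += 1
        sd = np.sqrt(1000 * 0.2 * 0.8)
        for e, c in counts.items():
            assert abs(c - 200) < 4 * sd


class TestKfoldSplits:
    def test_singleton_folds(self, ten_edge_net):
        splits = kfold_splits(ten_edge_net.edges(), k=10, seed=0)
        assert all(len(s.test_edges) == 1 for s in splits)

    def test_fold_sizes_differ_by_at_most_one(self, ten_edge_net):
        sizes = sorted(len(s.test_edges) for s in kfold_splits(ten_edge_net.edges(), 3))
        assert sizes == [3, 3, 4]

    def test_partition_law(self, ten_edge_net):
        splits = kfold_splits(ten_edge_net.edges(), k=4, seed=1)
        all_test = [e for s in splits for e in s.test_edges]
        assert sorted(all_test) == ten_edge_net.edges()
        assert len(set(all_test)) == len(all_test)

    def test_k_exceeding_edges_raises(self, ten_edge_net):
        with pytest.raises(MdcapError):
            kfold_splits(ten_edge_net.edges(), k=11)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_hand_counted_concordance(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs concordant
        r = roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        r = roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 1])
        assert r.auc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(MdcapError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_concordance(self, seed):
        """AUC equals the all-pairs Mann-Whitney count with 0.5 per tie."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        ) / (len(pos) * len(neg))
        assert roc_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(5 * scores) + 3, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_curve_is_monotone(self):
        rng = np.random.default_rng(1)
        r = roc_auc(rng.random(50), (rng.random(50) < 0.5).astype(int))
        fpr = [p[0] for p in r.roc_points]
        tpr = [p[1] for p in r.roc_points]
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))


class TestEvaluateSplit:
    def test_training_similarities_ignore_test_edges(self, planted):
        """Perturbing held-out edges leaves training-derived matrices bit-identical."""
        _, net, _, ontology = planted
        split = split_holdout(net, 0.2, seed=3)
        # two different perturbations of the test set, same training edges
        t1 = EdgeSplit(split.train_edges, split.test_edges[:-1], 3)
        t2 = EdgeSplit(split.train_edges, split.test_edges[1:], 3)
        cfg = MDCAPConfig()
        nets = [BipartiteNetwork.from_edges(s.train_edges) for s in (t1, t2)]
        sims = [integrated_similarities(n, ontology, cfg) for n in nets]
        for a, b in zip(sims[0], sims[1]):
            assert np.array_equal(a.values, b.values)

    def test_unseen_entity_edges_discarded(self):
        # mir-3's only edge is held out, so it is absent from training
        train = (("hsa-mir-1", "d1"), ("hsa-mir-1", "d2"), ("hsa-mir-2", "d1"),
                 ("hsa-mir-4", "d2"))
        test = (("hsa-mir-3", "d1"), ("hsa-mir-2", "d2"))
        res = evaluate_split(EdgeSplit(train, test, 0))
        assert res.n_discarded == 1
        assert res.n_pos == 1
        assert res.n_neg == 3 * 2 - len(train) - 1  # only (hsa-mir-4, d1) remains

    def test_all_positives_unseen_raises(self):
        split = EdgeSplit(
            (("hsa-mir-1", "d1"), ("hsa-mir-2", "d1")), (("hsa-mir-9", "d9"),), 0
        )
        with pytest.raises(MdcapError):
            evaluate_split(split)

    def test_negatives_exclude_train_and_test_edges(self, planted):
        _, net, _, ontology = planted
        split = split_holdout(net, 0.2, seed=1)
        res = evaluate_split(split, ontology)
        train_net = BipartiteNetwork.from_edges(split.train_edges)
        retained = [
            e for e in split.test_edges
            if e[0] in train_net.mirna_index and e[1] in train_net.disease_index
        ]
        n_pairs = len(train_net.mirnas) * len(train_net.diseases)
        assert res.n_pos == len(retained)
        assert res.n_neg == n_pairs - len(split.train_edges) - len(retained)

    def test_sampled_negative_mode(self, planted):
        _, net, _, ontology = planted
        split = split_holdout(net, 0.2, seed=1)
        res = evaluate_split(split, ontology, negative_mode="sampled", negative_ratio=2.0)
        assert res.n_neg == 2 * res.n_pos


class TestRepeatEvaluation:
    def test_single_repeat_equals_single_run(self, planted):
        _, net, _, ontology = planted
        summary = repeat_evaluation(net, "holdout", repeats=1, base_seed=9,
                                    ontology=ontology)
        single = evaluate_split(split_holdout(net, 0.2, 9), ontology)
        assert summary.aucs == [single.auc]
        assert summary.sd_auc == 0.0

    def test_reproducible_for_fixed_seed(self, planted):
        _, net, _, ontology = planted
        a = repeat_evaluation(net, "holdout", 2, 11, ontology)
        b = repeat_evaluation(net, "holdout", 2, 11, ontology)
        assert a.aucs == b.aucs

    def test_auc_stable_across_repeats(self, planted):
        """On the planted network the AUC sd over repeats stays small."""
        _, net, _, ontology = planted
        summary = repeat_evaluation(net, "holdout", repeats=10, base_seed=0,
                                    ontology=ontology)
        assert summary.sd_auc < 0.1
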