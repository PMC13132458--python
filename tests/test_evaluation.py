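"""Protocol layer: sampling, splits, metrics, noise, diagnostics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ddacl import evaluation as ev
from ddacl.errors import ConfigurationError, MetricError, SamplingError


def _pairs(n_drugs=6, n_dis=5, n_pos=8, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"d{k}" for k in range(n_drugs)]
    dis = [f"z{k}" for k in range(n_dis)]
    universe = [(a, b) for a in drugs for b in dis]
    idx = rng.choice(len(universe), size=n_pos, replace=False)
    pos = [universe[k] for k in idx]
    return drugs, dis, pos


class TestBalancedNegatives:
    def test_counts_and_disjointness(self):
        drugs, dis, pos = _pairs()
        labeled = ev.balanced_negatives(pos, drugs, dis, seed=1)
        positives = [p for p in labeled if p.label == 1]
        negatives = [p for p in labeled if p.label == 0]
        assert len(positives) == len(negatives) == len(pos)
        assert not ({p.key() for p in negatives} & set(pos))

    def test_seed_reproducibility(self):
        drugs, dis, pos = _pairs()
        a = ev.balanced_negatives(pos, drugs, dis, seed=9)
        b = ev.balanced_negatives(pos, drugs, dis, seed=9)
        assert [p.key() for p in a] == [p.key() for p in b]

    def test_uniform_sampling_frequencies(self):
        # 3x3 universe with 2 positives: each of 7 unknown pairs should be
        # drawn with probability 2/7 per draw of 2 negatives
        drugs = ["a", "b", "c"]
        dis = ["x", "y", "z"]
        pos = [("a", "x"), ("b", "y")]
        counts = {}
        n_rep = 300
        for seed in range(n_rep):
            for p in ev.balanced_negatives(pos, drugs, dis, seed=seed):
                if p.label == 0:
                    counts[p.key()] = counts.get(p.key(), 0) + 1
        assert len(counts) == 7
        expected = n_rep * 2 / 7
        sd = np.sqrt(n_rep * (2 / 7) * (5 / 7))
        for c in counts.values():
            assert abs(c - expected) < 5 * sd

    def test_insufficient_unknowns_raise(self):
        with pytest.raises(SamplingError):
            ev.balanced_negatives([("a", "x"), ("a", "y")], ["a"], ["x", "y"], seed=0)


class TestSplits:
    def test_cv_fold_sizes_and_coverage(self):
        drugs, dis, pos = _pairs(n_drugs=20, n_dis=10, n_pos=50)
        pairs = ev.balanced_negatives(pos, drugs, dis, seed=0)
        split = ev.make_cv_folds(pairs, k=5, seed=0)
        sizes = [len(te) for _, te in split.folds]
        assert sum(sizes) == len(pairs) and max(sizes) - min(sizes) <= 1
        tested = np.concatenate([te for _, te in split.folds])
        assert sorted(tested.tolist()) == list(range(len(pairs)))
        again = ev.make_cv_folds(pairs, k=5, seed=0)
        assert all(np.array_equal(a[1], b[1]) for a, b in zip(split.folds, again.folds))

    def test_cv_folds_are_label_stratified(self):
        drugs, dis, pos = _pairs(n_drugs=20, n_dis=10, n_pos=50)
        pairs = ev.balanced_negatives(pos, drugs, dis, seed=0)
        split = ev.make_cv_folds(pairs, k=5, seed=3)
        for _, te in split.folds:
            labs = [pairs[n].label for n in te]
            assert abs(sum(labs) - len(labs) / 2) <= 1

    def test_k_below_two_rejected(self):
        drugs, dis, pos = _pairs()
        pairs = ev.balanced_negatives(pos, drugs, dis, seed=0)
        with pytest.raises(ConfigurationError):
            ev.make_cv_folds(pairs, k=1)

    @pytest.mark.parametrize("mode", ["C1", "C2", "C3"])
    def test_coldstart_entity_exclusion(self, mode):
        drugs, dis, pos = _pairs(n_drugs=30, n_dis=20, n_pos=80, seed=2)
        pairs = ev.balanced_negatives(pos, drugs, dis, seed=2)
        split = ev.make_coldstart_split(pairs, mode=mode, fraction=0.2, seed=5)
        tr, te = split.folds[0]
        assert not (set(tr) & set(te))
        tr_drugs = {pairs[n].drug_id for n in tr}
        te_drugs = {pairs[n].drug_id for n in te}
        tr_dis = {pairs[n].disease_id for n in tr}
        te_dis = {pairs[n].disease_id for n in te}
        if mode in {"C1", "C3"}:
            assert not (tr_drugs & te_drugs)
        if mode in {"C2", "C3"}:
            assert not (tr_dis & te_dis)

    def test_c1_holds_out_the_right_number_of_drugs(self):
        drugs, dis, pos = _pairs(n_drugs=10, n_dis=12, n_pos=40, seed=4)
        pairs = ev.balanced_negatives(pos, drugs, dis, seed=4)
        split = ev.make_coldstart_split(pairs, mode="C1", fraction=0.2, seed=0)
        _, te = split.folds[0]
        te_drugs = {pairs[n].drug_id for n in te}
        all_drugs = {p.drug_id for p in pairs}
        assert len(te_drugs) <= max(1, round(0.2 * len(all_drugs)))
        # every pair of a held-out drug is in test
        for n, p in enumerate(pairs):
            if p.drug_id in te_drugs:
                assert n in set(te.tolist())


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        m = ev.classification_metrics(np.array([0.9, 0.8, 0.3, 0.1]),
                                      np.array([1, 1, 0, 0]), theta=0.5)
        assert m["auroc"] == pytest.approx(1.0)
        assert m["aupr"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(1.0)

    def test_half_concordant_example(self):
        # concordant pairs: (0.9,0.2), (0.9,0.8); discordant: (0.1,*) -> 2/4
        assert ev.auroc(np.array([0.9, 0.2, 0.8, 0.1]),
                        np.array([1, 0, 0, 1])) == pytest.approx(0.5)

    def test_constant_scores_tie_convention(self):
        assert ev.auroc(np.full(10, 0.3), np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            ev.auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(20))
    def test_rank_formula_matches_trapezoidal(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        assert ev.auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-9)


class TestRankingMetrics:
    def test_reciprocal_rank_and_p_r_at_k(self):
        rankings = {"q": (["c1", "c2", "c3", "c4"], {"c2", "c3"})}
        m = ev.ranking_metrics(rankings, k_values=(3,))
        assert m["mrr"] == pytest.approx(0.5)
        assert m["p_at_3"] == pytest.approx(2 / 3)
        assert m["r_at_3"] == pytest.approx(1.0)

    def test_ndcg_hand_value(self):
        # relevant at ranks 1 and 3 of 2 total relevant
        rankings = {"q": (["a", "b", "c", "d"], {"a", "c"})}
        m = ev.ranking_metrics(rankings)
        assert m["ndcg_at_10"] == pytest.approx(0.9197207891481876, abs=1e-9)

    def test_queries_without_relevant_are_excluded(self):
        rankings = {"q1": (["a", "b"], {"a"}), "q2": (["c", "d"], set())}
        m = ev.ranking_metrics(rankings)
        assert m["mrr"] == pytest.approx(1.0)

    def test_grouping_from_score_table(self):
        pairs = [ev.LabeledPair("d1", "z1", 1), ev.LabeledPair("d1", "z2", 0),
                 ev.LabeledPair("d2", "z1", 0), ev.LabeledPair("d2", "z2", 1)]
        rankings = ev.rankings_from_scores(pairs, [0, 1, 2, 3],
                                           [0.9, 0.1, 0.8, 0.2], by="drug")
        assert rankings["d1"][0] == ["z1", "z2"]
        assert rankings["d2"][1] == {"z2"}


class TestNoise:
    def test_rho_zero_is_identity(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        assert np.array_equal(ev.inject_noise(X, ev.NoiseSpec(rho=0.0)), X)

    def test_seed_reproducibility(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        spec = ev.NoiseSpec(rho=0.3, seed=11)
        assert np.array_equal(ev.inject_noise(X, spec), ev.inject_noise(X, spec))

    def test_relative_sd_calibration(self):
        rng = np.random.default_rng(2)
        X = rng.normal(scale=2.0, size=(100_000, 1))
        noisy = ev.inject_noise(X, ev.NoiseSpec(rho=0.5, seed=3))
        realized = (noisy - X).std()
        assert realized == pytest.approx(0.5 * X.std(), rel=0.02)

    def test_zero_variance_column_untouched(self):
        X = np.ones((50, 2))
        X[:, 1] = np.random.default_rng(4).normal(size=50)
        noisy = ev.inject_noise(X, ev.NoiseSpec(rho=0.4, seed=5))
        assert np.array_equal(noisy[:, 0], X[:, 0])


class TestQuality:
    def test_identical_unit_vectors_have_cosine_one(self):
        v = np.array([[0.6, 0.8]])
        q = ev.feature_quality([(0, 0)], [(0, 0)], v, v, seed=0)
        assert q.mean_pos_sim == pytest.approx(1.0)

    def test_pooled_sd_hand_value(self):
        assert ev.cohens_d(np.array([0.6, 0.8]), np.array([0.1, 0.3])) == pytest.approx(
            3.5355339059327378)

    def test_null_case_auc_near_half(self):
        rng = np.random.default_rng(6)
        vecs = rng.normal(size=(80, 8))
        pairs = [(k, (k + 1) % 80) for k in range(80)]
        q = ev.feature_quality(pairs[:40], pairs[40:], vecs, vecs, seed=0)
        assert abs(q.sim_auc - 0.5) < 0.2

    def test_clustering_perfect_agreement(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        labels = np.repeat([0, 1, 2], 30)
        X = centers[labels] + rng.normal(scale=0.1, size=(90, 2))
        q = ev.clustering_quality(X, labels, k=3, seed=0)
        assert q.nmi == pytest.approx(1.0)
        assert q.ari == pytest.approx(1.0)

    def test_clustering_k_above_n_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.clustering_quality(np.ones((3, 2)), [0, 1, 0], k=5)
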