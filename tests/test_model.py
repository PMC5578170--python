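import numpy as np
import pytest

import dtiwave as dw
from dtiwave import metrics
from dtiwave.errors import ConfigurationError, InputError

from conftest import mann_whitney_auc


class TestMetricIdentities:
    def test_confusion_formulas(self):
        c = metrics.ConfusionCounts(tp=45, fn=5, tn=40, fp=10)
        assert metrics.sensitivity(c) == pytest.approx(0.9)
        assert metrics.specificity(c) == pytest.approx(0.8)
        assert metrics.accuracy(c) == pytest.approx(0.85)

    def test_counts_from_labels(self):
        y = np.array([1, 1, -1, -1, 1])
        p = np.array([1, -1, -1, 1, 1])
        c = metrics.confusion_counts(y, p)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 1, 1)
        assert c.total == 5

    def test_trapezoidal_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            scores = rng.permutation(np.arange(400, dtype=float))  # tie-free
            y = np.where(rng.random(400) < 0.4, 1, -1)
            assert abs(metrics.roc_auc(y, scores) - mann_whitney_auc(y, scores)) < 1e-10

    def test_perfect_scorer(self):
        y = np.repeat([1, -1], 50)
        scores = y.astype(float)
        assert metrics.roc_auc(y, scores) == 1.0
        assert metrics.aupr(y, scores) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(14)
        y = np.repeat([1, -1], 1000)
        scores = rng.normal(size=2000)
        assert 0.45 <= metrics.roc_auc(y, scores) <= 0.55

    def test_curve_points_shapes(self):
        y = np.repeat([1, -1], 20)
        s = np.linspace(0, 1, 40)
        assert metrics.roc_points(y, s).shape[1] == 3
        assert metrics.pr_points(y, s).shape[1] == 2


class TestTrain:
    def test_separable_toy_reaches_training_accuracy_one(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(-3, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        y = np.repeat([-1, 1], 30)
        model = dw.train(X, y, C=8.0)
        assert np.array_equal(model.predict(X), y)

    def test_grid_choice_is_deterministic(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(-1, 1, (40, 3)), rng.normal(1, 1, (40, 3))])
        y = np.repeat([-1, 1], 40)
        m1 = dw.train(X, y, C="grid", gamma="grid", seed=4)
        m2 = dw.train(X, y, C="grid", gamma="grid", seed=4)
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(InputError):
            dw.train(X, np.ones(10, int))

    def test_selected_features_recorded_and_applied(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 8))
        X[:, 2] += np.repeat([2.0, -2.0], 30)
        y = np.repeat([1, -1], 30)
        model = dw.train(X, y, selected=np.array([2, 5]))
        assert model.decision_scores(X).shape == (60,)
        assert list(model.selected) == [2, 5]

    def test_probability_requires_calibration(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(40, 3))
        y = np.repeat([1, -1], 20)
        plain = dw.train(X, y)
        with pytest.raises(ConfigurationError):
            plain.probabilities(X)
        calibrated = dw.train(X, y, probability=True)
        p = calibrated.probabilities(X)
        assert np.all((p >= 0) & (p <= 1))


class TestEvaluateCV:
    def test_report_metric_identities_hold_per_fold(self, small_bench, small_bench_features):
        ds = dw.build_balanced(small_bench.network, 1, seed=0)[0]
        rep = dw.evaluate_cv(
            ds, small_bench.network, small_bench_features,
            small_bench.fingerprints, n_folds=5, seed=0,
        )
        for fm in rep.fold_metrics:
            total = fm["tp"] + fm["tn"] + fm["fp"] + fm["fn"]
            assert fm["acc"] == pytest.approx((fm["tp"] + fm["tn"]) / total)
            assert fm["sn"] == pytest.approx(fm["tp"] / (fm["tp"] + fm["fn"]))
            assert fm["spec"] == pytest.approx(fm["tn"] / (fm["tn"] + fm["fp"]))

    def test_same_seed_reproduces_report(self, small_bench, small_bench_features):
        ds = dw.build_balanced(small_bench.network, 1, seed=1)[0]
        kwargs = dict(n_folds=5, seed=1)
        r1 = dw.evaluate_cv(ds, small_bench.network, small_bench_features,
                            small_bench.fingerprints, **kwargs)
        r2 = dw.evaluate_cv(ds, small_bench.network, small_bench_features,
                            small_bench.fingerprints, **kwargs)
        np.testing.assert_array_equal(r1.pooled_scores, r2.pooled_scores)

    def test_masking_changes_training_features(self, small_bench):
        net = small_bench.network
        pos = net.positives()[:5]
        masked = dw.mask_test_edges(net, pos)
        assert masked.n_interactions == net.n_interactions - 5

    def test_summary_structure(self, small_bench, small_bench_features):
        ds = dw.build_balanced(small_bench.network, 1, seed=2)[0]
        rep = dw.evaluate_cv(ds, small_bench.network, small_bench_features,
                             small_bench.fingerprints, n_folds=5, seed=2)
        s = rep.summary()
        assert set(s) >= {"acc", "sn", "spec", "auc", "aupr", "n_folds"}
        assert s["n_folds"] == 5


class TestRankNovelPairs:
    @pytest.fixture()
    def trained(self, small_bench, small_bench_features):
        net = small_bench.network
        ds = dw.build_balanced(net, 1, seed=0)[0]
        X = dw.assemble_features(ds, net, small_bench_features, small_bench.fingerprints)
        return dw.train(X, ds.labels, C=8.0, seed=0)

    def test_top_n_larger_than_unknowns_returns_all(self, small_bench, small_bench_features, trained):
        top, full = dw.rank_novel_pairs(
            trained, small_bench.network, small_bench_features,
            small_bench.fingerprints, top_n=10**6,
        )
        n_unknown = len(small_bench.network.unknown_pairs())
        assert len(top) == len(full) == n_unknown

    def test_scores_sorted_desc_with_lexicographic_ties(self, small_bench, small_bench_features, trained):
        _, full = dw.rank_novel_pairs(
            trained, small_bench.network, small_bench_features,
            small_bench.fingerprints, top_n=5,
        )
        for a, b in zip(full, full[1:]):
            assert a[2] > b[2] or (a[2] == b[2] and (a[0], a[1]) < (b[0], b[1]))

    def test_held_out_true_edge_outranks_unmatched_pairs(self, table):
        # strong planted signal; hide one group-matched true edge, retrain,
        # and check it beats never-interacting unmatched-group pairs
        bench = dw.synthesize_benchmark(
            n_drugs=40, n_targets=30, n_edges=150, signal_strength=1.0, seed=23
        )
        net = bench.network
        feats = {
            tid: dw.target_features(dw.encode_sequence(seq, table, tid))
            for tid, seq in bench.sequences.items()
        }
        # held-out edge: a known interaction between group-matched partners
        held = next(
            (d, t) for d, t in net.positives()
            if bench.drug_groups[net.drug_index(d)]
            == bench.target_groups[net.target_index(t)]
        )
        masked = dw.mask_test_edges(net, [held])
        ds = dw.build_balanced(masked, 1, seed=3)[0]
        # keep the held-out pair out of the sampled negatives
        assert held not in [p for p, y in zip(ds.pairs, ds.labels) if y == -1]
        X = dw.assemble_features(ds, masked, feats, bench.fingerprints)
        model = dw.train(X, ds.labels, C=8.0, seed=3)
        _, full = dw.rank_novel_pairs(model, masked, feats, bench.fingerprints)
        score = {(d, t): s for d, t, s in full}
        unmatched = [
            (d, t) for d, t in masked.unknown_pairs()
            if bench.drug_groups[masked.drug_index(d)]
            != bench.target_groups[masked.target_index(t)]
        ][:2]
        for pair in unmatched:
            assert score[held] > score[pair]

    def test_empty_unknown_set(self, small_bench_features, small_bench):
        net = dw.InteractionNetwork(
            drug_ids=["a"], target_ids=["x"], adjacency=np.ones((1, 1), int)
        )
        # trained model irrelevant: no unknown pairs to score
        top, full = dw.rank_novel_pairs(None, net, {}, {})
        assert top == [] and full == []
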