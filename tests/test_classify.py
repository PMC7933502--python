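import numpy as np
import pytest
from scipy.stats import binomtest

from fmsc.classify import (
    ConfusionCounts,
    consensus_connections,
    cross_validate,
    metrics_from_confusion,
    stratified_kfold,
)
from fmsc.core import FmscError, pair_to_flat_index, vectorize_upper_triangle
from fmsc.functional import build_fcn
from fmsc.simulate import SimConfig, simulate_cohort


class TestStratifiedKfold:
    def test_partition_properties_for_unbalanced_cohort(self):
        labels = np.array([1] * 24 + [0] * 23)
        folds = stratified_kfold(labels, k=10, seed=0)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen.tolist()) == list(range(47))
        for tr, te in folds:
            assert len(te) in (4, 5)
            assert set(tr) | set(te) == set(range(47))
            assert not set(tr) & set(te)
            # stratification: each class within 1 of proportional share
            assert labels[te].sum() in (2, 3)

    def test_leave_one_out_with_balanced_labels(self):
        labels = np.array([0, 1] * 4)
        folds = stratified_kfold(labels, k=8, seed=3)
        assert all(len(te) == 1 for _, te in folds)

    def test_deterministic_given_seed(self):
        labels = np.array([0] * 12 + [1] * 13)
        a = stratified_kfold(labels, 5, seed=9)
        b = stratified_kfold(labels, 5, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(FmscError):
            stratified_kfold(np.array([0] * 3 + [1] * 20), k=10, seed=0)


class TestConfusionMetrics:
    def test_printed_formula_case(self):
        acc, prec, f1 = metrics_from_confusion(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert acc == pytest.approx(0.7)
        assert prec == pytest.approx(0.75)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))

    def test_perfect_and_all_wrong(self):
        assert metrics_from_confusion(ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0)
        acc, _, _ = metrics_from_confusion(ConfusionCounts(0, 5, 0, 5))
        assert acc == 0.0

    def test_no_positive_predictions_scores_zero_precision(self, caplog):
        acc, prec, f1 = metrics_from_confusion(ConfusionCounts(TP=0, FP=0, TN=4, FN=2))
        assert prec == 0.0 and f1 == 0.0
        assert acc == pytest.approx(4 / 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(FmscError):
            ConfusionCounts(-1, 0, 0, 1)


class TestCrossValidate:
    def test_strong_single_feature_reaches_high_accuracy(self):
        """One feature with 4-SD group separation: mean accuracy over seeded
        runs is at least 95% and the feature is selected in every fold."""
        accs = []
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            labels = np.array([0] * 20 + [1] * 20)
            X = rng.standard_normal((40, 30))
            X[labels == 1, 7] += 4.0
            rep = cross_validate(X, labels, k=10, seed=s)
            accs.append(rep.accuracy_pct)
            assert all(7 in fr.selected_features for fr in rep.per_fold)
        assert np.mean(accs) >= 95.0

    def test_pure_noise_stays_at_chance_over_seeds(self):
        """Null simulation: pooled out-of-fold accuracy sits inside the 95%
        binomial interval of 50% over 20 seeds."""
        correct = total = 0
        for s in range(20):
            rng = np.random.default_rng(900 + s)
            labels = np.array([0] * 23 + [1] * 24)
            X = rng.standard_normal((47, 100))
            rep = cross_validate(X, labels, k=10, seed=s)
            pred, _ = rep.subject_predictions(47)
            correct += int((pred == labels).sum())
            total += 47
        assert binomtest(correct, total, 0.5).pvalue >= 0.05

    def test_duplicated_subjects_keep_aggregate_accuracy(self, rng):
        labels = np.array([0] * 12 + [1] * 12)
        X = rng.standard_normal((24, 20))
        X[labels == 1, 3] += 4.0
        rep = cross_validate(X, labels, k=6, seed=1)
        X2 = np.vstack([X, X])
        labels2 = np.concatenate([labels, labels])
        rep2 = cross_validate(X2, labels2, k=6, seed=1)
        assert abs(rep.accuracy_pct - rep2.accuracy_pct) <= 10.0

    def test_test_fold_data_cannot_leak_into_selection_or_fit(self, rng):
        """Corrupting a fold's held-out feature rows leaves that fold's
        selected features and train t-statistics unchanged: only training
        data enters selection and fitting."""
        labels = np.array([0] * 12 + [1] * 12)
        X = rng.standard_normal((24, 15))
        X[labels == 1, 2] += 2.0
        rep = cross_validate(X, labels, k=4, seed=5)
        te0 = rep.per_fold[0].test_indices
        X_corrupt = X.copy()
        X_corrupt[te0] = 1000.0 * X_corrupt[te0] + 77.0
        rep_c = cross_validate(X_corrupt, labels, k=4, seed=5)
        assert np.array_equal(
            rep_c.per_fold[0].selected_features, rep.per_fold[0].selected_features
        )
        np.testing.assert_allclose(rep_c.per_fold[0].train_t, rep.per_fold[0].train_t)
        # other folds now train on corrupted rows, so only fold 0 is compared

    def test_empty_selection_falls_back_to_all_features(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 4))
        rep = cross_validate(X, labels, k=5, seed=0, alpha=1e-12)
        assert all(fr.fallback_all_features for fr in rep.per_fold)
        assert all(fr.selected_features.size == 4 for fr in rep.per_fold)

    def test_aggregate_is_mean_of_folds(self, rng):
        labels = np.array([0] * 15 + [1] * 15)
        X = rng.standard_normal((30, 10))
        rep = cross_validate(X, labels, k=5, seed=0)
        assert rep.accuracy_pct == pytest.approx(
            100 * np.mean([fr.accuracy for fr in rep.per_fold])
        )

    def test_report_dict_roundtrips_to_json(self, rng, tmp_path):
        labels = np.array([0] * 8 + [1] * 8)
        X = rng.standard_normal((16, 6))
        rep = cross_validate(X, labels, k=4, seed=0)
        path = tmp_path / "r.json"
        rep.save(path)
        import json

        d = json.loads(path.read_text())
        assert d["aggregate"]["accuracy_pct"] == pytest.approx(rep.accuracy_pct)
        assert len(d["per_fold"]) == 4


class TestConsensusConnections:
    def test_feature_must_be_selected_in_every_fold(self, rng):
        labels = np.array([0] * 20 + [1] * 20)
        X = rng.standard_normal((40, 10))
        X[labels == 1, 4] += 4.0  # always selected
        rep = cross_validate(X, labels, k=10, seed=0)
        # count fold occurrences per feature
        counts = {}
        for fr in rep.per_fold:
            for idx in fr.selected_features:
                counts[int(idx)] = counts.get(int(idx), 0) + 1
        cons = consensus_connections(rep, m=5, top_n=10)
        cons_idx = {c["flat_index"] for c in cons}
        for idx, n in counts.items():
            if n == 10:
                assert idx in cons_idx
            else:
                assert idx not in cons_idx

    def test_injected_edges_recovered_in_top10(self):
        """Three planted functional-connectivity deltas appear in the
        consensus top-10 in at least 90% of seeded end-to-end runs."""
        edges = ((2, 9), (10, 21), (5, 30))
        inj = {pair_to_flat_index(i, j, 34) for i, j in edges}
        hits = 0
        runs = 10
        for s in range(runs):
            cfg = SimConfig(seed=3_000 + s, fc_effects=tuple((e, 0.4) for e in edges))
            _, series, labels, _ = simulate_cohort(cfg)
            X = np.vstack(
                [vectorize_upper_triangle(build_fcn(ts)) for ts in series]
            )
            rep = cross_validate(X, labels, k=10, seed=s)
            top = {c["flat_index"] for c in consensus_connections(rep, 34)}
            hits += int(inj <= top)
        assert hits / runs >= 0.9

    def test_k1_consensus_is_that_folds_selection(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 6))
        X[labels == 1, 1] += 3.0
        rep = cross_validate(X, labels, k=2, seed=0)
        rep.per_fold = rep.per_fold[:1]
        cons = consensus_connections(rep, m=4, top_n=100)
        assert {c["flat_index"] for c in cons} == set(
            int(i) for i in rep.per_fold[0].selected_features
        )

    def test_empty_consensus_warns_and_returns_empty(self, rng, caplog):
        labels = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 6))
        rep = cross_validate(X, labels, k=5, seed=2, alpha=1e-12)
        # fallback selects everything, so force disjoint selections
        rep.per_fold[0].selected_features = np.array([0])
        rep.per_fold[1].selected_features = np.array([1])
        assert consensus_connections(rep, m=4) == []
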