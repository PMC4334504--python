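import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmforest.ensemble import (
    EnsembleModel,
    RFParams,
    compute_metrics,
    make_undersampled_subsets,
    metrics_from_counts,
    predict_vote,
    stratified_cv,
    train_ensemble,
)
from ecmforest.io_formats import FeatureMatrix, load_model, save_model


class TestSubsets:
    def test_reference_imbalance_gives_eleven_groups(self):
        pos = [f"p{i}" for i in range(410)]
        neg = [f"n{i}" for i in range(4464)]
        subsets = make_undersampled_subsets(pos, neg, seed=0)
        assert len(subsets) == 11

    def test_balanced_input_single_group(self):
        subsets = make_undersampled_subsets([f"p{i}" for i in range(10)],
                                            [f"n{i}" for i in range(10)], seed=0)
        assert len(subsets) == 1

    def test_near_equal_split(self):
        pos = [f"p{i}" for i in range(5)]
        neg = [f"n{i}" for i in range(23)]
        subsets = make_undersampled_subsets(pos, neg, seed=1)
        assert len(subsets) == 5
        neg_sizes = sorted(len(s) - 5 for s in subsets)
        assert neg_sizes == [4, 4, 5, 5, 5]

    def test_negatives_partitioned_positives_duplicated(self):
        pos = [f"p{i}" for i in range(7)]
        neg = [f"n{i}" for i in range(40)]
        subsets = make_undersampled_subsets(pos, neg, seed=2)
        seen_negs = [sid for s in subsets for sid in s if sid.startswith("n")]
        assert sorted(seen_negs) == sorted(neg)  # exactly once each
        for s in subsets:
            assert set(pos) <= set(s)

    def test_reproducible_under_seed(self):
        pos, neg = ["a", "b"], [f"n{i}" for i in range(9)]
        assert make_undersampled_subsets(pos, neg, 5) == make_undersampled_subsets(pos, neg, 5)
        assert make_undersampled_subsets(pos, neg, 5) != make_undersampled_subsets(pos, neg, 6)


class TestMetrics:
    def test_balanced_accuracy_identity_first_row(self):
        # counts constructed to give Sn = 0.893 and Sp = 0.799 exactly
        report = metrics_from_counts(tp=893, tn=799, fp=201, fn=107)
        assert report.sn == pytest.approx(0.893)
        assert report.sp == pytest.approx(0.799)
        assert report.bacc == pytest.approx(0.846)
        assert report.acc == pytest.approx(0.846)

    def test_balanced_accuracy_identity_second_row(self):
        report = metrics_from_counts(tp=854, tn=850, fp=150, fn=146)
        assert report.sn == pytest.approx(0.854)
        assert report.sp == pytest.approx(0.850)
        assert report.bacc == pytest.approx(0.852)

    def test_perfect_prediction(self):
        y = [1, 1, 0, 0]
        report = compute_metrics(y, y)
        assert (report.sn, report.sp, report.acc, report.bacc) == (1, 1, 1, 1)

    def test_undefined_rates_are_nan(self):
        report = compute_metrics([1, 1], [1, 0])
        assert math.isnan(report.sp) and math.isnan(report.bacc)
        assert report.sn == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [1])

    @settings(deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_identities_on_random_counts(self, counts):
        tp, tn, fp, fn = counts
        report = metrics_from_counts(tp, tn, fp, fn)
        if tp + fn:
            assert abs(report.sn - tp / (tp + fn)) < 1e-12
        if tn + fp:
            assert abs(report.sp - tn / (tn + fp)) < 1e-12
        if tp + tn + fp + fn:
            assert abs(report.acc - (tp + tn) / (tp + tn + fp + fn)) < 1e-12
        if (tp + fn) and (tn + fp):
            assert abs(report.bacc - (report.sn + report.sp) / 2) < 1e-12


def _planted_matrix(rng, n_pos, n_neg, shift=2.0, d=8):
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [0] * n_neg)
    values = rng.normal(size=(n, d))
    values[: n_pos, :3] += shift  # first three features carry the signal
    return FeatureMatrix([f"s{i}" for i in range(n)],
                         [f"f{j}" for j in range(d)], values, labels)


class TestTrainPredict:
    def test_member_count_matches_imbalance(self):
        rng = np.random.default_rng(0)
        m = _planted_matrix(rng, 10, 110)
        model = train_ensemble(m, seed=0)
        assert model.n_members == 11

    def test_balanced_fixture_single_member(self):
        rng = np.random.default_rng(1)
        model = train_ensemble(_planted_matrix(rng, 15, 15), seed=0)
        assert model.n_members == 1

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(2)
        m = _planted_matrix(rng, 12, 40)
        probe = _planted_matrix(np.random.default_rng(3), 5, 5)
        p1, _ = predict_vote(train_ensemble(m, seed=9), probe)
        p2, _ = predict_vote(train_ensemble(m, seed=9), probe)
        assert np.array_equal(p1, p2)

    def test_majority_and_tie_rules(self):
        class Stub:
            def __init__(self, vote):
                self.vote = vote

            def predict(self, X):
                return np.full(len(X), self.vote)

        m = _planted_matrix(np.random.default_rng(4), 3, 3, d=2)
        model = EnsembleModel(tuple(Stub(v) for v in [1] * 6 + [0] * 5),
                              ("f0", "f1"), seed=0)
        labels, votes = predict_vote(model, m)
        assert np.all(labels == 1) and np.all(votes == 6)

        tied = EnsembleModel((Stub(1), Stub(0)), ("f0", "f1"), seed=0)
        labels, votes = predict_vote(tied, m)
        assert np.all(labels == 1)  # even split goes positive

        unanimous = EnsembleModel((Stub(0), Stub(0)), ("f0", "f1"), seed=0)
        labels, votes = predict_vote(unanimous, m)
        assert np.all(labels == 0) and np.all(votes == 0)

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(5)
        m = _planted_matrix(rng, 10, 10)
        with pytest.raises(KeyError):
            train_ensemble(m, feature_subset=["nope"], seed=0)

    def test_model_roundtrip_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        m = _planted_matrix(rng, 12, 36)
        model = train_ensemble(m, seed=4)
        probe = _planted_matrix(np.random.default_rng(7), 6, 6)
        before, _ = predict_vote(model, probe)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        after, _ = predict_vote(loaded, probe)
        assert np.array_equal(before, after)
        assert loaded.feature_names == model.feature_names


class TestCV:
    def test_every_sample_tested_exactly_once(self):
        rng = np.random.default_rng(8)
        m = _planted_matrix(rng, 20, 40)
        report = stratified_cv(m, folds=5, seed=0)
        total = report.tp + report.tn + report.fp + report.fn
        assert total == m.n_samples
        assert report.tp + report.fn == 20  # all positives tested
        assert report.tn + report.fp == 40

    def test_strong_separation_recovered(self):
        rng = np.random.default_rng(9)
        m = _planted_matrix(rng, 25, 25, shift=3.0)
        report = stratified_cv(m, folds=5, seed=1)
        assert report.bacc >= 0.9

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(10)
        m = _planted_matrix(rng, 50, 50, shift=0.0)
        report = stratified_cv(m, folds=5, seed=2)
        assert abs(report.bacc - 0.5) <= 0.1

    def test_class_smaller_than_folds_rejected(self):
        rng = np.random.default_rng(11)
        m = _planted_matrix(rng, 3, 40)
        with pytest.raises(ValueError, match="fewer"):
            stratified_cv(m, folds=5, seed=0)

    def test_k1_ensemble_equals_single_forest(self):
        # balanced data: the ensemble has one member trained on all rows,
        # which is exactly the single-forest pipeline
        rng = np.random.default_rng(12)
        m = _planted_matrix(rng, 20, 20, shift=1.0)
        a = stratified_cv(m, folds=4, seed=3, use_ensemble=True)
        b = stratified_cv(m, folds=4, seed=3, use_ensemble=False)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)


class TestRFParams:
    def test_log2_rule(self):
        assert RFParams().resolve_max_features(315) == int(math.log2(315)) + 1
        assert RFParams().resolve_max_features(1) == 1
        assert RFParams(max_features=5).resolve_max_features(3) == 3
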