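"""Classifier training, relabeling, metrics, and cohort-level summaries."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.tree import DecisionTreeClassifier

from sprstress.classify import (ModelSpec, compute_metrics, loso_evaluate,
                                predict_sequence, relabel, stress_percentage,
                                train)
from sprstress.features import FEATURE_NAMES, FeatureVector, LabeledFeatureSet
from sprstress.pipeline import RunConfig, process_subject, simulate_cohort

FAMILIES = ("svm", "random_forest", "decision_tree")


def separable_set(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    X[n // 2:] += 6.0
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestTrain:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_data_fit_perfectly(self, family):
        X, y = separable_set()
        model = train(ModelSpec(family=family, cv_folds=5), X, y)
        assert np.array_equal(predict_sequence(model, X), y)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train(ModelSpec(cv_folds=2), X, np.zeros(10, dtype=int))

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 80) > 0).astype(int)
        a = train(ModelSpec(family="svm", cv_folds=5, seed=9), X, y)
        b = train(ModelSpec(family="svm", cv_folds=5, seed=9), X, y)
        assert a.best_params_ == b.best_params_

    def test_permuted_labels_give_chance_accuracy(self):
        """Cross-validated accuracy on label-permuted data stays near 50%."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 8))
            y = rng.permutation(np.repeat([0, 1], 60))
            accs.append(cross_val_score(DecisionTreeClassifier(random_state=0),
                                        X, y, cv=5).mean())
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="naive_bayes")


class TestPredictSequence:
    def test_empty_input_empty_output(self):
        X, y = separable_set()
        model = train(ModelSpec(family="decision_tree", cv_folds=5), X, y)
        assert len(predict_sequence(model, np.empty((0, 2)))) == 0

    def test_length_preserved_and_constant_on_identical_rows(self):
        X, y = separable_set()
        model = train(ModelSpec(family="decision_tree", cv_folds=5), X, y)
        rows = np.tile(X[0], (7, 1))
        out = predict_sequence(model, rows)
        assert len(out) == 7 and len(np.unique(out)) == 1

    def test_feature_mismatch_rejected(self):
        X, y = separable_set()
        model = train(ModelSpec(family="decision_tree", cv_folds=5), X, y)
        with pytest.raises(ValueError):
            predict_sequence(model, np.zeros((3, 5)))


class TestRelabel:
    @pytest.mark.parametrize("seq,expected", [
        ([0, 1, 0], [0, 0, 0]),
        ([1, 1, 0, 1, 1], [1, 1, 1, 1, 1]),
        ([1, 1, 1], [1, 1, 1]),
        ([0, 0, 0, 0], [0, 0, 0, 0]),
        ([1, 0, 1, 0, 1], [1, 1, 1, 1, 1]),
        ([0, 1], [0, 1]),
    ])
    def test_isolated_singleton_rule(self, seq, expected):
        assert relabel(np.array(seq)).tolist() == expected

    def test_endpoints_never_change_and_idempotent(self, rng):
        for _ in range(50):
            seq = rng.integers(0, 2, size=rng.integers(2, 30))
            out = relabel(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]
            np.testing.assert_array_equal(relabel(out), out)

    def test_reduces_isolated_singletons(self, rng):
        def isolated(s):
            return sum(s[i - 1] == s[i + 1] != s[i] for i in range(1, len(s) - 1))
        for _ in range(50):
            seq = rng.integers(0, 2, size=20)
            assert isolated(relabel(seq)) <= isolated(seq)


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.accuracy, m.sensitivity, m.specificity,
                m.balanced_accuracy, m.geometric_mean) == (100,) * 5

    def test_hand_computed_contingency_table(self):
        # TP=3, FN=1, TN=4, FP=2
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        m = compute_metrics(y_true, y_pred)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(200 / 3)
        assert m.accuracy == pytest.approx(70.0)
        assert m.balanced_accuracy == pytest.approx(70.833, abs=1e-3)
        assert m.geometric_mean == pytest.approx(70.71, abs=0.005)

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(0, 2, 40)
        y_true[:2] = [0, 1]
        y_pred = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        assert compute_metrics(y_true, y_pred) == compute_metrics(y_true[perm],
                                                                  y_pred[perm])

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [1, 0, 1])


def toy_subject(subject_id, seed):
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for k in range(40):
        label = int(k >= 20)  # contiguous runs, stable under relabel
        base = 3.0 * label + rng.normal(0, 0.3)
        vals = dict(zip(FEATURE_NAMES, base + rng.normal(0, 0.2, 8)))
        vectors.append(FeatureVector(**vals, block_start_s=5.0 * k,
                                     block_end_s=5.0 * k + 15.0))
        labels.append(label)
    return LabeledFeatureSet(vectors=vectors, labels=np.array(labels),
                             subject_id=subject_id, scenario="traffic")


class TestLoso:
    def test_identical_separable_subjects_score_100(self):
        datasets = [toy_subject("A", 1), toy_subject("B", 1)]
        per, mean, pooled = loso_evaluate(datasets,
                                          ModelSpec(family="decision_tree", cv_folds=5))
        assert mean.accuracy == pytest.approx(100.0)
        assert pooled.accuracy == pytest.approx(100.0)

    def test_mean_is_average_of_per_subject_metrics(self):
        datasets = [toy_subject(s, i) for i, s in enumerate("ABC")]
        per, mean, _ = loso_evaluate(datasets,
                                     ModelSpec(family="decision_tree", cv_folds=5))
        assert mean.balanced_accuracy == pytest.approx(
            np.mean([m.balanced_accuracy for m in per.values()]))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_evaluate([toy_subject("A", 1)], ModelSpec())

    def test_synthetic_cohort_mean_ba_at_least_70(self):
        """Leave-one-person-out on a simulated cohort discriminates stress
        blocks well above chance (fixture threshold 70% BA)."""
        cfg = RunConfig(n_subjects=5, sim=replace(RunConfig().sim, duration_s=300),
                        seed=21, compute_scalograms=False)
        datasets = []
        for recs in simulate_cohort(cfg):
            datasets.extend(process_subject(recs, cfg).feature_sets.values())
        _, mean, _ = loso_evaluate(datasets,
                                   ModelSpec(family="decision_tree", cv_folds=5))
        assert mean.balanced_accuracy >= 70.0


class TestStressPercentage:
    def test_all_zero_labels(self):
        blocks = [(0.0, 15.0), (5.0, 20.0)]
        s = stress_percentage(np.zeros(2, dtype=int), blocks)
        assert s.pct_positive_total == 0.0

    def test_seven_of_twenty(self):
        blocks = [(5.0 * k, 5.0 * k + 15.0) for k in range(20)]
        labels = np.zeros(20, dtype=int)
        labels[:7] = 1
        assert stress_percentage(labels, blocks).pct_positive_total == pytest.approx(35.0)

    def test_sections_partition_total(self):
        blocks = [(5.0 * k, 5.0 * k + 15.0) for k in range(20)]
        labels = (np.arange(20) % 3 == 0).astype(int)
        sections = [(0.0, 50.0, "highway"), (50.0, 120.0, "city")]
        s = stress_percentage(labels, blocks, sections)
        n_high = sum(1 for b, _ in blocks if b < 50.0)
        weighted = (s.pct_positive_by_section["highway"] * n_high
                    + s.pct_positive_by_section["city"] * (20 - n_high)) / 20
        assert weighted == pytest.approx(s.pct_positive_total)

    def test_zero_blocks_rejected(self):
        with pytest.raises(ValueError):
            stress_percentage(np.empty(0, dtype=int), [])
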