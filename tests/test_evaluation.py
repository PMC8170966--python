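import math
import warnings

import numpy as np
import pytest

from nucleocgr.evaluation import (
    ConfusionCounts,
    PipelineConfig,
    auc_score,
    confusion_from_predictions,
    cross_validate,
    metrics_from_confusion,
    stratified_kfold,
)
from nucleocgr.synthetic_data import GeneratorSpec, generate_dataset


def direct_metrics(tp, tn, fp, fn):
    """Literal re-derivation of the four confusion-matrix metrics."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return sn, sp, acc, mcc


def pairwise_auc(labels, scores):
    """O(n^2) pairwise oracle with 0.5 tie credit."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics_from_confusion(ConfusionCounts(50, 50, 0, 0))
        assert (r.Sn, r.Sp, r.ACC, r.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        r = metrics_from_confusion(ConfusionCounts(45, 45, 5, 5))
        assert r.ACC == pytest.approx(0.9)
        assert r.Sn == pytest.approx(0.9)
        assert r.Sp == pytest.approx(0.9)
        assert r.MCC == pytest.approx(0.8)

    def test_degenerate_denominators_warn_and_zero(self):
        # no true or predicted positives: Sn and the MCC denominator are 0/0
        with pytest.warns(UserWarning):
            r = metrics_from_confusion(ConfusionCounts(0, 0, 5, 0))
        assert r.Sn == 0.0
        assert r.MCC == 0.0
        # all-wrong balanced case: denominators are fine, MCC hits its floor
        r2 = metrics_from_confusion(ConfusionCounts(0, 0, 5, 5))
        assert r2.ACC == 0.0
        assert r2.MCC == -1.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))

    def test_enumeration_matches_direct_formula(self):
        rng_cases = [
            (tp, tn, fp, fn)
            for tp in range(0, 11, 2)
            for tn in range(0, 11, 2)
            for fp in range(0, 11, 2)
            for fn in range(0, 11, 2)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tp, tn, fp, fn in rng_cases:
                if tp + tn + fp + fn == 0:
                    continue
                r = metrics_from_confusion(ConfusionCounts(tp, tn, fp, fn))
                sn, sp, acc, mcc = direct_metrics(tp, tn, fp, fn)
                assert r.Sn == pytest.approx(sn, abs=1e-12)
                assert r.Sp == pytest.approx(sp, abs=1e-12)
                assert r.ACC == pytest.approx(acc, abs=1e-12)
                assert r.MCC == pytest.approx(mcc, abs=1e-12)
                assert -1.0 <= r.MCC <= 1.0

    def test_mcc_symmetries(self):
        """Swapping TP<->TN with FP<->FN preserves MCC; label flip negates it."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tp, tn, fp, fn in [(7, 3, 2, 5), (1, 9, 0, 4), (6, 6, 6, 6)]:
                m = metrics_from_confusion(ConfusionCounts(tp, tn, fp, fn)).MCC
                swapped = metrics_from_confusion(ConfusionCounts(tn, tp, fn, fp)).MCC
                flipped = metrics_from_confusion(ConfusionCounts(fn, fp, tn, tp)).MCC
                assert m == pytest.approx(swapped, abs=1e-12)
                assert m == pytest.approx(-flipped, abs=1e-12)


class TestAUC:
    def test_extremes(self):
        labels = np.array([1, 1, 0, 0])
        assert auc_score(labels, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
        assert auc_score(labels, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, 100)
            labels[:2] = [0, 1]
            scores = rng.choice(np.linspace(0, 1, 25), 100)  # forces ties
            assert auc_score(labels, scores) == pytest.approx(
                pairwise_auc(labels, scores), abs=1e-12
            )

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.normal(size=60)  # continuous: no ties
        assert auc_score(labels, scores) == pytest.approx(
            1 - auc_score(labels, -scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(np.ones(5, dtype=int), np.arange(5.0))


class TestStratifiedKFold:
    def test_exact_divisibility(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = stratified_kfold(labels, 10, seed=0)
        for f in range(10):
            assert (labels[folds == f] == 1).sum() == 5
            assert (labels[folds == f] == 0).sum() == 5

    def test_remainder_rule(self):
        labels = np.array([1] * 52 + [0] * 50)
        folds = stratified_kfold(labels, 10, seed=0)
        pos_counts = [(labels[folds == f] == 1).sum() for f in range(10)]
        neg_counts = [(labels[folds == f] == 0).sum() for f in range(10)]
        assert set(pos_counts) <= {5, 6} and sum(pos_counts) == 52
        assert set(neg_counts) == {5}

    def test_deterministic(self):
        labels = np.array([1] * 30 + [0] * 30)
        np.testing.assert_array_equal(
            stratified_kfold(labels, 5, seed=9), stratified_kfold(labels, 5, seed=9)
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([1, 1, 0, 0, 0]), 3, seed=0)


class TestCrossValidate:
    def test_every_sample_scored_once(self, small_dataset):
        cfg = PipelineConfig(
            features=[{"kind": "fcgr", "Ks": [2]}],
            classifier="xgboost",
            clf_params={"n_trees": 20},
        )
        res = cross_validate(small_dataset, cfg, k=5, seed=0)
        assert np.isfinite(res.oof_scores).all()
        assert len(res.oof_scores) == len(small_dataset)
        assert len(res.per_fold) == 5
        # pooled counts partition the dataset
        counts = confusion_from_predictions(
            np.array(small_dataset.labels), (res.oof_scores >= 0.5).astype(int)
        )
        assert counts.total == len(small_dataset)

    def test_separable_dataset_recovered(self, small_dataset):
        cfg = PipelineConfig(
            features=[{"kind": "fcgr", "Ks": [2]}],
            classifier="svm",
            clf_params={"C_grid": (1.0, 10.0), "gamma_grid": (0.05, 0.5)},
        )
        res = cross_validate(small_dataset, cfg, k=5, seed=0)
        assert res.pooled.ACC >= 0.95
        assert res.pooled.AUC >= 0.98

    def test_image_backend_runs(self, small_dataset):
        cfg = PipelineConfig(classifier="mlp", image_Ks=[2], clf_params={"epochs": 3})
        res = cross_validate(small_dataset, cfg, k=3, seed=0)
        assert np.isfinite(res.oof_scores).all()

    def test_pca_in_pipeline(self, small_dataset):
        cfg = PipelineConfig(
            features=[{"kind": "fcgr", "Ks": [2]}],
            classifier="xgboost",
            clf_params={"n_trees": 20},
            pca_rate=0.95,
        )
        res = cross_validate(small_dataset, cfg, k=3, seed=0)
        assert np.isfinite(res.oof_scores).all()

    def test_unknown_classifier(self, small_dataset):
        with pytest.raises(ValueError):
            cross_validate(small_dataset, PipelineConfig(classifier="forest"), k=2, seed=0)
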