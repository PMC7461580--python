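"""Splitting, metrics, ROC/Youden oracles, and leak-free cross-validation."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from arpcm.evaluation import (
    CutoffSet,
    classification_report,
    cross_validate,
    mcc_multiclass,
    roc_ovr,
    stratified_split,
    youden_cutoffs,
)
from arpcm.exceptions import EmptyInputError
from arpcm.models import BaselineConfig


def auc_by_pair_counting(scores, binary):
    """Probability that a random positive outscores a random negative
    (ties count half) — the rank interpretation of AUC."""
    pos = scores[binary == 1]
    neg = scores[binary == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_exhaustive(scores, binary):
    """Best J over every candidate threshold by brute-force scan."""
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]])
    best = (-np.inf, None)
    n_pos, n_neg = binary.sum(), (1 - binary).sum()
    for thr in candidates:
        pred = scores >= thr
        j = (pred & (binary == 1)).sum() / n_pos + ((~pred) & (binary == 0)).sum() / n_neg - 1
        if j > best[0] + 1e-12:
            best = (j, thr)
    return best


class TestStratifiedSplit:
    def test_eighty_twenty(self, rng):
        y = rng.integers(0, 4, size=100)
        plan = stratified_split(y, test_fraction=0.2, seed=0)
        assert len(plan.test_idx) == pytest.approx(20, abs=3)
        assert len(plan.train_idx) + len(plan.test_idx) == 100
        assert not set(plan.train_idx) & set(plan.test_idx)

    def test_single_stratum_still_splits(self):
        y = np.zeros(50, dtype=int)
        plan = stratified_split(y, test_fraction=0.2, seed=1)
        assert len(plan.test_idx) == 10

    def test_drugs_on_both_sides(self, rng):
        y = rng.integers(0, 2, size=60)
        drugs = rng.choice(["a", "b", "c"], size=60)
        plan = stratified_split(y, drugs, seed=2)
        for d in "abc":
            rows = np.flatnonzero(drugs == d)
            assert np.isin(rows, plan.train_idx).any()
            assert np.isin(rows, plan.test_idx).any()

    def test_singleton_drug_goes_to_train(self):
        y = np.array([0, 0, 0, 0, 1])
        drugs = np.array(["a", "a", "a", "a", "rare"])
        with pytest.warns(UserWarning, match="single member"):
            plan = stratified_split(y, drugs, seed=0)
        assert 4 in plan.train_idx

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            stratified_split([])


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3] * 5)
        r = classification_report(y, y)
        assert r.weighted_f1 == r.weighted_precision == r.weighted_recall == 1.0
        assert r.mcc == 1.0
        np.testing.assert_array_equal(r.confusion, np.eye(4) * 5)

    def test_never_predicted_class_gets_zero_precision(self):
        true = np.array([0, 0, 2, 2, 1, 1])
        pred = np.array([0, 0, 0, 0, 1, 1])  # class 2 never predicted
        r = classification_report(true, pred)
        assert r.precision[2] == 0.0 and r.recall[2] == 0.0 and r.f1[2] == 0.0

    def test_hand_computed_three_class_toy(self):
        # confusion: true 0 -> [3,1,0]; true 1 -> [1,2,0]; true 2 -> [0,1,2]
        true = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        pred = np.array([0, 0, 0, 1, 0, 1, 1, 1, 2, 2])
        r = classification_report(true, pred)
        assert r.precision[0] == pytest.approx(3 / 4)
        assert r.recall[0] == pytest.approx(3 / 4)
        assert r.precision[1] == pytest.approx(2 / 4)
        assert r.recall[1] == pytest.approx(2 / 3)
        assert r.precision[2] == pytest.approx(2 / 2)
        assert r.recall[2] == pytest.approx(2 / 3)
        assert r.f1[1] == pytest.approx(2 * (0.5 * 2 / 3) / (0.5 + 2 / 3))
        # weighted averages use true-class support
        assert r.weighted_recall == pytest.approx((4 * 0.75 + 3 * 2 / 3 + 3 * 2 / 3) / 10)
        assert r.n_samples == 10

    def test_weighted_recall_equals_accuracy(self, rng):
        true = rng.integers(0, 4, size=80)
        pred = rng.integers(0, 4, size=80)
        r = classification_report(true, pred)
        assert r.weighted_recall == pytest.approx((true == pred).mean())

    def test_confusion_conservation(self, rng):
        true = rng.integers(0, 4, size=60)
        pred = rng.integers(0, 4, size=60)
        r = classification_report(true, pred)
        assert r.confusion.sum() == 60
        np.testing.assert_array_equal(r.confusion.sum(axis=1), r.support)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_report([0, 1], [0])


class TestMCC:
    def test_perfect_and_constant(self):
        y = np.array([0, 1, 2, 3] * 4)
        assert mcc_multiclass(y, y) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert mcc_multiclass(y, np.zeros_like(y)) == 0.0

    def test_matches_sklearn_on_random_labels(self, rng):
        for _ in range(20):
            true = rng.integers(0, 4, size=50)
            pred = rng.integers(0, 4, size=50)
            assert mcc_multiclass(true, pred) == pytest.approx(
                matthews_corrcoef(true, pred), abs=1e-12
            )

    def test_reduces_to_binary_formula(self, rng):
        true = rng.integers(0, 2, size=40)
        pred = rng.integers(0, 2, size=40)
        tp = ((true == 1) & (pred == 1)).sum()
        tn = ((true == 0) & (pred == 0)).sum()
        fp = ((true == 0) & (pred == 1)).sum()
        fn = ((true == 1) & (pred == 0)).sum()
        denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        expected = (tp * tn - fp * fn) / denom if denom else 0.0
        assert mcc_multiclass(true, pred) == pytest.approx(expected, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        proba = np.zeros((10, 4))
        proba[:, 1] = np.concatenate([np.full(5, 0.1), np.full(5, 0.9)])
        proba[:, 0] = 1 - proba[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roc = roc_ovr(proba, y)
        assert roc.auc[0] == pytest.approx(1.0)
        assert roc.auc[1] == pytest.approx(1.0)
        assert np.isnan(roc.auc[2]) and np.isnan(roc.auc[3])

    def test_null_scores_give_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        proba = np.zeros((2000, 4))
        proba[:, 1] = rng.random(2000)  # independent of labels
        proba[:, 0] = 1 - proba[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roc = roc_ovr(proba, y)
        assert roc.auc[1] == pytest.approx(0.5, abs=0.05)

    def test_trapezoid_equals_pair_counting(self, rng):
        """AUC via trapezoidal ROC integration must equal the probability of
        concordant ordering counted over all positive-negative pairs."""
        for _ in range(10):
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(30), 2)  # ties included
            proba = np.zeros((30, 4))
            proba[:, 1] = scores
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                roc = roc_ovr(proba, y)
            assert roc.auc[1] == pytest.approx(auc_by_pair_counting(scores, y), abs=1e-10)

    def test_mean_curve_shape(self, rng):
        y = rng.integers(0, 4, size=100)
        proba = rng.dirichlet(np.ones(4), size=100)
        roc = roc_ovr(proba, y)
        assert roc.mean_fpr.shape == roc.mean_tpr.shape == roc.sd_tpr.shape == (101,)
        assert roc.mean_tpr[0] == 0.0 and roc.mean_tpr[-1] == 1.0


class TestYouden:
    def test_perfectly_separated_groups(self):
        y = np.array([0] * 10 + [1] * 10)
        proba = np.zeros((20, 4))
        proba[:, 1] = np.concatenate([np.full(10, 0.1), np.full(10, 0.9)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cuts = youden_cutoffs(proba, y)
        assert 0.1 < cuts.values[1] < 0.9
        pred = proba[:, 1] >= cuts.values[1]
        assert (pred == (y == 1)).all()  # J = 1 at the returned cutoff

    def test_matches_exhaustive_scan(self, rng):
        """The returned cutoff must achieve the same J as a brute-force scan
        over every candidate threshold."""
        for _ in range(10):
            y = rng.integers(0, 2, size=25)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(25), 2)
            proba = np.zeros((25, 4))
            proba[:, 1] = scores
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cuts = youden_cutoffs(proba, y)
            best_j, best_thr = youden_exhaustive(scores, y)
            pred = scores >= cuts.values[1]
            n_pos, n_neg = y.sum(), (1 - y).sum()
            got_j = (pred & (y == 1)).sum() / n_pos + ((~pred) & (y == 0)).sum() / n_neg - 1
            assert got_j == pytest.approx(best_j, abs=1e-12)
            assert cuts.values[1] == pytest.approx(best_thr)

    def test_degenerate_scores_warn(self):
        y = np.array([0, 0, 1, 1])
        proba = np.full((4, 4), 0.25)
        with pytest.warns(UserWarning, match="degenerate"):
            cuts = youden_cutoffs(proba, y)
        assert cuts.values[0] == 0.5

    def test_cutoffset_validation(self):
        with pytest.raises(ValueError):
            CutoffSet((0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            CutoffSet((0.1, 0.2, 0.3, 1.4))


class _SpyModel:
    """Records the matrices it is asked to score."""

    def __init__(self):
        self.seen = []

    def predict_proba(self, X):
        self.seen.append(X.copy())
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=len(X))
        return p


class TestCrossValidate:
    def test_fold_sizes_and_partition(self, blobs_4class):
        X, y = blobs_4class
        cv = cross_validate(
            X, y, BaselineConfig(model_kind="rf", seed=0), k=5, seed=0,
            oversample=False,
        )
        sizes = [len(f.val_idx) for f in cv.folds]
        assert max(sizes) - min(sizes) <= 1
        all_val = np.concatenate([f.val_idx for f in cv.folds])
        assert sorted(all_val) == list(range(len(y)))

    def test_validation_rows_bit_identical(self, blobs_4class):
        """With no scaling/oversampling, the model must be scored on the raw
        validation rows exactly; inputs are never mutated either way."""
        X, y = blobs_4class
        X_before = X.copy()
        spy = _SpyModel()
        cv = cross_validate(
            X, y, k=5, seed=0, oversample=False, standardize=False,
            model_factory=lambda Xt, yt: spy,
        )
        np.testing.assert_array_equal(X, X_before)
        for fold, seen in zip(cv.folds, spy.seen):
            np.testing.assert_array_equal(seen, X[fold.val_idx])

    def test_oversampling_confined_to_training_portion(self, blobs_4class):
        """Resampled training rows grow to k×majority; the validation fold is
        scored at its original size, so no synthetic row is ever validated."""
        X, y = blobs_4class
        # make it imbalanced: drop most of class 3
        keep = np.flatnonzero((y != 3) | (np.arange(len(y)) % 5 == 0))
        X, y = X[keep], y[keep]
        cv = cross_validate(
            X, y, BaselineConfig(model_kind="rf", seed=0), k=5, seed=0,
            oversample=True,
        )
        for fold in cv.folds:
            assert fold.n_train_resampled > len(fold.train_idx)
            assert len(fold.proba) == len(fold.val_idx)

    def test_separable_data_high_mean_auc(self, blobs_4class):
        X, y = blobs_4class
        cv = cross_validate(
            X, y, BaselineConfig(model_kind="rf", seed=0), k=5, seed=0,
            oversample=False,
        )
        assert cv.mean_macro_auc >= 0.95

    def test_k_too_small(self, blobs_4class):
        X, y = blobs_4class
        with pytest.raises(ValueError):
            cross_validate(X, y, k=1)
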