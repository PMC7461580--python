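"""Splitting, cross-validation, ROC/Youden calibration, and metrics.

The evaluation protocol mirrors the training study: one stratified 80/20
train/test split (every drug represented on both sides when counts permit),
5-fold cross-validation on the training portion with the standardizer and
the oversampler fitted inside each fold's training part only, one-vs-rest
ROC with a macro-averaged mean curve, per-class Youden's J cutoffs, and a
classification report with per-class and support-weighted precision/recall/
F1, multiclass Matthews correlation, and a confusion matrix (rows = true
class, columns = predicted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_curve
from sklearn.model_selection import StratifiedKFold

from .descriptors import Standardizer
from .exceptions import EmptyInputError
from .models import (
    N_CLASSES,
    BaselineConfig,
    DNNConfig,
    TrainedClassifier,
    predict_proba,
    train_baseline,
    train_dnn,
)
from .resampling import borderline_smote

#: FPR grid the mean ROC curve is averaged on.
MEAN_ROC_GRID = np.linspace(0.0, 1.0, 101)


# -- splitting ---------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test index sets."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float


def stratified_split(
    labels: Sequence[int],
    drug_ids: Sequence[str] | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/test split by (class, drug) strata.

    Each stratum contributes test rows proportionally (±1 sample); singleton
    strata go to the training side with a warning.  A post-pass moves one row
    where needed so every drug with ≥2 samples appears on both sides.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise EmptyInputError("cannot split an empty dataset")
    drugs = np.asarray(drug_ids if drug_ids is not None else [""] * len(y))
    rng = np.random.default_rng(seed)

    test: list[int] = []
    train: list[int] = []
    strata: dict[tuple[int, str], np.ndarray] = {}
    for key in {(int(c), str(d)) for c, d in zip(y, drugs)}:
        strata[key] = np.flatnonzero((y == key[0]) & (drugs == key[1]))
    for key in sorted(strata):
        idx = strata[key]
        if len(idx) < 2:
            warnings.warn(
                f"stratum {key} has a single member; kept in the training set",
                stacklevel=2,
            )
            train.extend(idx.tolist())
            continue
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 0), len(idx) - 1)
        perm = rng.permutation(idx)
        test.extend(perm[:n_test].tolist())
        train.extend(perm[n_test:].tolist())

    train_a = np.asarray(sorted(train), dtype=int)
    test_a = np.asarray(sorted(test), dtype=int)
    # tiny datasets can leave the test side empty after per-stratum rounding;
    # fall back to a per-class proportional draw so evaluation stays possible
    if len(test_a) == 0 and len(y) >= 5:
        moved = []
        for cls in np.unique(y):
            rows = np.intersect1d(np.flatnonzero(y == cls), train_a)
            n_mv = min(max(1, int(round(len(rows) * test_fraction))), len(rows) - 1)
            if n_mv > 0:
                moved.extend(rng.choice(rows, size=n_mv, replace=False).tolist())
        test_a = np.asarray(sorted(moved), dtype=int)
        train_a = np.setdiff1d(train_a, test_a)
    # drug-presence repair: every drug with >=2 rows should appear on both sides
    if drug_ids is not None:
        for d in np.unique(drugs):
            d_rows = np.flatnonzero(drugs == d)
            if len(d_rows) < 2:
                continue
            if not np.isin(d_rows, test_a).any():
                movable = np.intersect1d(d_rows, train_a)
                pick = rng.choice(movable)
                train_a = train_a[train_a != pick]
                test_a = np.sort(np.append(test_a, pick))
            elif not np.isin(d_rows, train_a).any():
                movable = np.intersect1d(d_rows, test_a)
                pick = rng.choice(movable)
                test_a = test_a[test_a != pick]
                train_a = np.sort(np.append(train_a, pick))
    return SplitPlan(train_idx=train_a, test_idx=test_a, test_fraction=test_fraction)


# -- metrics -----------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-class and weighted classification metrics plus the confusion matrix."""

    precision: np.ndarray  # per class, codes 0..3
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    mcc: float
    confusion: np.ndarray  # rows = true, cols = predicted
    auc_per_class: dict[int, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(c): {
                    "precision": float(self.precision[c]),
                    "recall": float(self.recall[c]),
                    "f1": float(self.f1[c]),
                    "support": int(self.support[c]),
                }
                for c in range(N_CLASSES)
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "mcc": self.mcc,
            "confusion_matrix": self.confusion.tolist(),
            "auc_per_class": {str(k): v for k, v in self.auc_per_class.items()},
        }


def classification_report(
    true: Sequence[int], predicted: Sequence[int]
) -> EvaluationReport:
    """Precision/recall/F1 per class (zero-division → 0), weighted averages,
    multiclass MCC, and the 4×4 confusion matrix."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if len(true) != len(predicted):
        raise ValueError(f"length mismatch: {len(true)} vs {len(predicted)}")
    labels = list(range(N_CLASSES))
    p, r, f1, sup = precision_recall_fscore_support(
        true, predicted, labels=labels, zero_division=0
    )
    total = sup.sum()
    wp = float((p * sup).sum() / total) if total else 0.0
    wr = float((r * sup).sum() / total) if total else 0.0
    wf = float((f1 * sup).sum() / total) if total else 0.0
    return EvaluationReport(
        precision=p,
        recall=r,
        f1=f1,
        support=sup,
        weighted_precision=wp,
        weighted_recall=wr,
        weighted_f1=wf,
        mcc=mcc_multiclass(true, predicted),
        confusion=_sk_confusion(true, predicted, labels=labels),
    )


def mcc_multiclass(true: Sequence[int], predicted: Sequence[int]) -> float:
    """Matthews correlation, covariance (Gorodkin) generalization.

    Computed from the confusion matrix C as
    ``(n·tr(C) − Σ_k t_k p_k) / sqrt((n² − Σ p_k²)(n² − Σ t_k²))`` where
    ``t_k``/``p_k`` are true/predicted class totals.  A zero denominator
    (degenerate truth or prediction) returns 0 with a warning.
    """
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if len(true) != len(predicted):
        raise ValueError("length mismatch")
    C = _sk_confusion(true, predicted, labels=list(range(N_CLASSES))).astype(float)
    n = C.sum()
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    cov = n * np.trace(C) - (t * p).sum()
    denom = np.sqrt((n**2 - (p**2).sum()) * (n**2 - (t**2).sum()))
    if denom == 0:
        warnings.warn("degenerate labels: MCC undefined, returning 0", stacklevel=2)
        return 0.0
    return float(cov / denom)


# -- ROC and cutoffs ---------------------------------------------------------


@dataclass
class RocResult:
    """One-vs-rest ROC per class plus the macro-averaged mean curve."""

    fpr: dict[int, np.ndarray]
    tpr: dict[int, np.ndarray]
    auc: dict[int, float]  # NaN where undefined
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray

    @property
    def macro_auc(self) -> float:
        vals = [a for a in self.auc.values() if np.isfinite(a)]
        return float(np.mean(vals)) if vals else float("nan")


def roc_ovr(proba: np.ndarray, labels: Sequence[int]) -> RocResult:
    """One-vs-rest ROC curves with trapezoidal AUC.

    Classes with only one outcome get an undefined (NaN) AUC instead of a
    crash.  The mean curve is the vertical average of per-class TPR over a
    fixed 101-point FPR grid with a standard-deviation band.
    """
    proba = np.asarray(proba, dtype=float)
    y = np.asarray(labels, dtype=int)
    fprs, tprs, aucs = {}, {}, {}
    interp = []
    for c in range(N_CLASSES):
        binary = (y == c).astype(int)
        if binary.min() == binary.max():
            warnings.warn(f"class {c}: AUC undefined (single outcome)", stacklevel=2)
            aucs[c] = float("nan")
            continue
        fpr, tpr, _ = roc_curve(binary, proba[:, c])
        fprs[c], tprs[c] = fpr, tpr
        aucs[c] = float(_sk_auc(fpr, tpr))
        interp.append(np.interp(MEAN_ROC_GRID, fpr, tpr))
    if interp:
        stack = np.vstack(interp)
        mean_tpr, sd_tpr = stack.mean(axis=0), stack.std(axis=0)
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    else:
        mean_tpr = np.full_like(MEAN_ROC_GRID, np.nan)
        sd_tpr = np.full_like(MEAN_ROC_GRID, np.nan)
    return RocResult(
        fpr=fprs, tpr=tprs, auc=aucs,
        mean_fpr=MEAN_ROC_GRID.copy(), mean_tpr=mean_tpr, sd_tpr=sd_tpr,
    )


@dataclass(frozen=True)
class CutoffSet:
    """One decision threshold in [0, 1] per phenotype code."""

    values: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.values) != N_CLASSES or any(not 0 <= v <= 1 for v in self.values):
            raise ValueError(f"cutoffs must be {N_CLASSES} values in [0, 1]")

    def __iter__(self):
        return iter(self.values)


def youden_cutoffs(proba: np.ndarray, labels: Sequence[int]) -> CutoffSet:
    """Per-class threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidates are 0, 1 and all midpoints between adjacent sorted unique
    scores of that class; a sample counts positive when its score reaches the
    threshold.  Ties resolve to the lowest threshold.  A class with a single
    outcome (or all-identical scores, which makes every threshold equivalent)
    gets the neutral cutoff 0.5 with a warning.
    """
    proba = np.asarray(proba, dtype=float)
    y = np.asarray(labels, dtype=int)
    cutoffs = []
    for c in range(N_CLASSES):
        binary = (y == c).astype(int)
        scores = proba[:, c]
        uniq = np.unique(scores)
        if binary.min() == binary.max() or len(uniq) == 1:
            warnings.warn(f"class {c}: degenerate scores/labels, cutoff 0.5", stacklevel=2)
            cutoffs.append(0.5)
            continue
        candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
        best_j, best_thr = -np.inf, 0.0
        n_pos = binary.sum()
        n_neg = len(binary) - n_pos
        for thr in candidates:
            pred = scores >= thr
            tp = int((pred & (binary == 1)).sum())
            tn = int((~pred & (binary == 0)).sum())
            j = tp / n_pos + tn / n_neg - 1.0
            if j > best_j + 1e-12:
                best_j, best_thr = j, float(thr)
        cutoffs.append(best_thr)
    return CutoffSet(tuple(cutoffs))


# -- cross-validation --------------------------------------------------------


@dataclass
class FoldResult:
    train_idx: np.ndarray
    val_idx: np.ndarray
    report: EvaluationReport
    roc: RocResult
    proba: np.ndarray  # validation-fold probabilities
    n_train_resampled: int


@dataclass
class CVResult:
    """Per-fold reports plus the fold-averaged mean ROC curve."""

    folds: list[FoldResult]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray

    @property
    def mean_macro_auc(self) -> float:
        vals = [f.roc.macro_auc for f in self.folds if np.isfinite(f.roc.macro_auc)]
        return float(np.mean(vals)) if vals else float("nan")

    def oof_proba(self, n: int) -> np.ndarray:
        """Out-of-fold probability matrix aligned with the input rows."""
        out = np.zeros((n, N_CLASSES))
        for f in self.folds:
            out[f.val_idx] = f.proba
        return out


ModelFactory = Callable[[np.ndarray, np.ndarray], object]


def _default_factory(config: DNNConfig | BaselineConfig):
    def factory(X: np.ndarray, y: np.ndarray):
        if isinstance(config, DNNConfig):
            clf, _ = train_dnn(X, y, config)
        else:
            clf = train_baseline(X, y, config)
        return clf
    return factory


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    config: DNNConfig | BaselineConfig | None = None,
    k: int = 5,
    seed: int = 0,
    boundary: int | None = None,
    oversample: bool = True,
    standardize: bool = True,
    model_factory: ModelFactory | None = None,
) -> CVResult:
    """Leak-free stratified k-fold cross-validation.

    For each fold the standardizer is fitted and borderline-SMOTE applied on
    the training portion only; the validation fold is scored untouched (its
    raw rows are transformed with training-fold statistics but never used to
    fit anything).  ``model_factory`` overrides the model construction and
    must return an object exposing ``predict_proba``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if config is None and model_factory is None:
        config = BaselineConfig(model_kind="rf", seed=seed)
    factory = model_factory or _default_factory(config)
    boundary = X.shape[1] if boundary is None else boundary

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    interp = []
    for fold_i, (tr, va) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        X_va = X[va]
        if standardize:
            scaler = Standardizer(boundary).fit(X_tr)
            X_tr_s = scaler.transform(X_tr)
            X_va_s = scaler.transform(X_va)
        else:
            X_tr_s, X_va_s = X_tr, X_va
        if oversample:
            X_tr_s, y_tr = borderline_smote(X_tr_s, y_tr, seed=seed + fold_i)
        model = factory(X_tr_s, y_tr)
        if isinstance(model, TrainedClassifier):
            proba = predict_proba(model, X_va_s)
        else:
            proba = np.asarray(model.predict_proba(X_va_s), dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roc = roc_ovr(proba, y[va])
            report = classification_report(y[va], proba.argmax(axis=1))
            report.auc_per_class = roc.auc
        folds.append(
            FoldResult(
                train_idx=tr, val_idx=va, report=report, roc=roc,
                proba=proba, n_train_resampled=len(X_tr_s),
            )
        )
        if np.isfinite(roc.mean_tpr).all():
            interp.append(roc.mean_tpr)
    if interp:
        stack = np.vstack(interp)
        mean_tpr, sd_tpr = stack.mean(axis=0), stack.std(axis=0)
    else:
        mean_tpr = np.full_like(MEAN_ROC_GRID, np.nan)
        sd_tpr = np.full_like(MEAN_ROC_GRID, np.nan)
    return CVResult(folds=folds, mean_fpr=MEAN_ROC_GRID.copy(), mean_tpr=mean_tpr, sd_tpr=sd_tpr)


def plot_mean_roc(cv: CVResult, ax=None, label: str | None = None):
    """Plot the fold-averaged ROC with its ±1 sd band (returns the axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(cv.mean_fpr, cv.mean_tpr, label=label or f"mean ROC (AUC={cv.mean_macro_auc:.2f})")
    ax.fill_between(
        cv.mean_fpr,
        np.clip(cv.mean_tpr - cv.sd_tpr, 0, 1),
        np.clip(cv.mean_tpr + cv.sd_tpr, 0, 1),
        color="grey",
        alpha=0.3,
    )
    ax.plot([0, 1], [0, 1], "--", color="k", linewidth=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    return ax
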