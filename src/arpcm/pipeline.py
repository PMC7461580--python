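"""High-level modelling facade and the prediction workflow.

:class:`PhenotypeModel` bundles a featurized mutant-drug dataset (built from
files, from a simulated dataset, or from raw arrays) and its ``fit`` method
runs the full training protocol — stratified 80/20 split, train-only
standardization, train-only borderline-SMOTE, model training, optional
Youden-calibrated decision cutoffs — returning a :class:`PhenotypeResults`
that carries the held-out evaluation report, a ``summary()`` table, and
prediction/persistence methods.  :func:`predict_pairs` replays a saved
model's featurization verbatim on new mutant-drug pairs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .curves import DoseResponseCurve, PhenotypeLabel, RuleThresholds, label_dataset
from .descriptors import Standardizer, featurize_pairs
from .evaluation import (
    CutoffSet,
    CVResult,
    EvaluationReport,
    RocResult,
    SplitPlan,
    classification_report,
    cross_validate,
    roc_ovr,
    stratified_split,
    youden_cutoffs,
)
from .exceptions import DimensionError
from .io import EXPORT_CODES
from .models import (
    BaselineConfig,
    DNNConfig,
    TrainedClassifier,
    load_classifier,
    predict_label,
    predict_proba,
    save_classifier,
    train_baseline,
    train_dnn,
)
from .mutants import MutantSpec, TrimRegion
from .nn import TrainingHistory


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted mutant-drug pair with its export coding."""

    mutant_id: str
    drug_id: str
    label: PhenotypeLabel
    proba: tuple[float, float, float, float]

    @property
    def export_code(self) -> int | None:
        """−1 = antagonized, 0 = non-responsive, 1 = mixed-response;
        agonist has no code in this scheme (None)."""
        return EXPORT_CODES.get(self.label)


class PhenotypeModel:
    """A featurized mutant-drug phenotype dataset ready for model fitting.

    Parameters
    ----------
    X : (n_pairs, n_features) raw (unstandardized) feature matrix
    y : phenotype codes 0..3 per pair
    boundary : first fingerprint column (end of the z-scale block)
    pairs : (mutant_id, drug_id) per row, used for stratification and reports
    region : trim window the protein block was computed on
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[int],
        boundary: int,
        pairs: Sequence[tuple[str, str]] | None = None,
        region: TrimRegion | None = None,
        wt_sequence: str | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise DimensionError("X and y disagree on the number of pairs")
        self.boundary = int(boundary)
        self.pairs = list(pairs) if pairs is not None else [("?", "?")] * len(self.y)
        self.region = region
        self.wt_sequence = wt_sequence

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_curves(
        cls,
        wt_sequence: str,
        curves: Sequence[DoseResponseCurve],
        specs: Sequence[MutantSpec],
        smiles_by_drug: Mapping[str, str],
        thresholds: RuleThresholds | None = None,
    ) -> "PhenotypeModel":
        """Label curves with the rule classifier and featurize the pairs."""
        records = label_dataset(curves, thresholds)
        pairs = [(r.mutant_id, r.drug_id) for r in records]
        y = [int(r.label) for r in records]
        X, boundary, region = featurize_pairs(wt_sequence, specs, smiles_by_drug, pairs)
        return cls(X, y, boundary, pairs=pairs, region=region, wt_sequence=wt_sequence)

    @classmethod
    def from_dataset(cls, dataset, thresholds: RuleThresholds | None = None) -> "PhenotypeModel":
        """Build from a :class:`arpcm.simulate.SimulatedDataset`."""
        return cls.from_curves(
            dataset.wt_sequence,
            dataset.curves,
            dataset.specs,
            dataset.smiles_by_drug,
            thresholds,
        )

    @classmethod
    def from_files(
        cls,
        wt_fasta: str | Path,
        mutants_path: str | Path,
        drugs_path: str | Path,
        curves_path: str | Path,
        thresholds: RuleThresholds | None = None,
    ) -> "PhenotypeModel":
        from . import io

        return cls.from_curves(
            io.read_wt_fasta(wt_fasta),
            io.read_curves(curves_path),
            io.read_mutants(mutants_path),
            io.read_drugs(drugs_path),
            thresholds,
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        method: str = "dnn",
        config: DNNConfig | BaselineConfig | None = None,
        seed: int = 0,
        test_fraction: float = 0.2,
        oversample: bool = True,
        cutoffs: str | CutoffSet = "auto",
        run_cv: bool = False,
        cv_folds: int = 5,
    ) -> "PhenotypeResults":
        """Run the full training protocol and evaluate on the held-out split.

        ``cutoffs="auto"`` calibrates per-class Youden thresholds for the
        shallow baselines from out-of-fold training predictions; the DNN
        always predicts by argmax (pass a :class:`CutoffSet` to override).
        """
        if method not in ("dnn", "svm", "rf"):
            raise ValueError(f"method must be dnn/svm/rf, got {method!r}")
        if config is None:
            config = (
                DNNConfig(seed=seed)
                if method == "dnn"
                else BaselineConfig(model_kind=method, seed=seed)
            )
        drug_ids = [d for _, d in self.pairs]
        split = stratified_split(self.y, drug_ids, test_fraction=test_fraction, seed=seed)
        X_tr_raw, y_tr = self.X[split.train_idx], self.y[split.train_idx]
        X_te_raw, y_te = self.X[split.test_idx], self.y[split.test_idx]

        scaler = Standardizer(self.boundary).fit(X_tr_raw)
        X_tr = scaler.transform(X_tr_raw)
        X_te = scaler.transform(X_te_raw)

        cv_result = None
        cutoff_set: CutoffSet | None = None
        if run_cv or (cutoffs == "auto" and method in ("svm", "rf")):
            cv_result = cross_validate(
                X_tr_raw, y_tr, config, k=cv_folds, seed=seed,
                boundary=self.boundary, oversample=oversample,
            )
        if isinstance(cutoffs, CutoffSet):
            cutoff_set = cutoffs
        elif cutoffs == "auto" and method in ("svm", "rf"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cutoff_set = youden_cutoffs(cv_result.oof_proba(len(y_tr)), y_tr)
        elif cutoffs not in ("auto", "none"):
            raise ValueError(f"cutoffs must be 'auto', 'none' or a CutoffSet, got {cutoffs!r}")

        if oversample:
            from .resampling import borderline_smote

            X_fit, y_fit = borderline_smote(X_tr, y_tr, seed=seed)
        else:
            X_fit, y_fit = X_tr, y_tr

        history = None
        if method == "dnn":
            clf, history = train_dnn(X_fit, y_fit, config)
        else:
            clf = train_baseline(X_fit, y_fit, config)

        proba_te = predict_proba(clf, X_te)
        pred_te = predict_label(proba_te, cutoff_set)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = classification_report(y_te, pred_te)
            roc = roc_ovr(proba_te, y_te)
            report.auc_per_class = roc.auc
        return PhenotypeResults(
            model=self,
            method=method,
            config=config,
            classifier=clf,
            scaler=scaler,
            split=split,
            cutoffs=cutoff_set,
            report=report,
            roc=roc,
            history=history,
            cv_result=cv_result,
            seed=seed,
        )


@dataclass
class PhenotypeResults:
    """Fitted phenotype classifier with its held-out evaluation."""

    model: PhenotypeModel
    method: str
    config: DNNConfig | BaselineConfig
    classifier: TrainedClassifier
    scaler: Standardizer
    split: SplitPlan
    cutoffs: CutoffSet | None
    report: EvaluationReport
    roc: RocResult
    history: TrainingHistory | None
    cv_result: CVResult | None
    seed: int

    def predict_proba_raw(self, X_raw: np.ndarray) -> np.ndarray:
        """Probabilities for raw (unstandardized) feature rows."""
        return predict_proba(self.classifier, self.scaler.transform(X_raw))

    def predict_records(
        self,
        specs: Sequence[MutantSpec],
        smiles_by_drug: Mapping[str, str],
        pairs: Sequence[tuple[str, str]] | None = None,
    ) -> list[PredictionRecord]:
        """Predict phenotypes for new mutant-drug pairs."""
        if self.model.wt_sequence is None:
            raise ValueError("model was built from arrays; no sequence to featurize")
        return _predict_records(
            self.classifier, self.scaler, self.model.region, self.cutoffs,
            self.model.wt_sequence, specs, smiles_by_drug, pairs,
        )

    def save(self, model_dir: str | Path) -> Path:
        extra = {}
        if self.cutoffs is not None:
            extra["cutoffs"] = list(self.cutoffs)
        if self.model.wt_sequence is not None:
            extra["wt_sequence"] = self.model.wt_sequence
        return save_classifier(
            self.classifier, model_dir, scaler=self.scaler,
            region=self.model.region, extra=extra,
        )

    def summary(self) -> str:
        """Plain-text summary table of the held-out evaluation."""
        r = self.report
        lines = []
        title = f"Phenotype classification results — {self.method.upper()}"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"pairs: {len(self.model.y)} total, "
            f"{len(self.split.train_idx)} train / {len(self.split.test_idx)} test"
        )
        lines.append(f"features: {self.model.X.shape[1]} "
                     f"(z-scale block {self.model.boundary}, fingerprint 2048)")
        if self.history is not None:
            lines.append(
                f"training stopped at epoch {self.history.stopped_epoch} "
                f"(best {self.history.best_epoch})"
            )
        if self.cutoffs is not None:
            lines.append("cutoffs (Youden): "
                         + ", ".join(f"{v:.3g}" for v in self.cutoffs))
        lines.append("")
        lines.append(f"{'class':<16}{'P':>8}{'R':>8}{'F1':>8}{'n':>6}")
        for c, lab in enumerate(PhenotypeLabel):
            lines.append(
                f"{lab.label:<16}{r.precision[c]:>8.2f}{r.recall[c]:>8.2f}"
                f"{r.f1[c]:>8.2f}{r.support[c]:>6d}"
            )
        lines.append(
            f"{'weighted avg':<16}{r.weighted_precision:>8.2f}"
            f"{r.weighted_recall:>8.2f}{r.weighted_f1:>8.2f}{r.n_samples:>6d}"
        )
        lines.append(f"MCC: {r.mcc:.3f}")
        finite = {c: a for c, a in r.auc_per_class.items() if np.isfinite(a)}
        if finite:
            lines.append(
                "AUC (one-vs-rest): "
                + ", ".join(f"class {c}: {a:.2f}" for c, a in sorted(finite.items()))
            )
        return "\n".join(lines)


def _predict_records(
    clf: TrainedClassifier,
    scaler: Standardizer | None,
    region: TrimRegion | None,
    cutoffs: CutoffSet | Sequence[float] | None,
    wt_sequence: str,
    specs: Sequence[MutantSpec],
    smiles_by_drug: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None,
) -> list[PredictionRecord]:
    if region is not None:
        for spec in specs:
            for pos in spec.positions:
                if not region.contains(pos):
                    raise DimensionError(
                        f"mutant {spec.mutant_id}: position {pos} lies outside "
                        f"the model's trim region [{region.start}, {region.end}]; "
                        "the model cannot represent it"
                    )
    if pairs is None:
        pairs = [(s.mutant_id, d) for s in specs for d in sorted(smiles_by_drug)]
    X, _, _ = featurize_pairs(wt_sequence, specs, smiles_by_drug, pairs, region=region)
    if scaler is not None:
        X = scaler.transform(X)
    proba = predict_proba(clf, X)
    labels = predict_label(proba, list(cutoffs) if cutoffs is not None else None)
    return [
        PredictionRecord(m, d, PhenotypeLabel(int(lab)), tuple(float(p) for p in row))
        for (m, d), lab, row in zip(pairs, labels, proba)
    ]


def predict_pairs(
    model_dir: str | Path,
    wt_sequence: str,
    specs: Sequence[MutantSpec],
    smiles_by_drug: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PredictionRecord]:
    """Predict phenotypes for new pairs with a saved model directory.

    The manifest's trim region, scaler and cutoffs are applied verbatim so
    prediction-time featurization matches training exactly.
    """
    clf, scaler, region = load_classifier(model_dir)
    cutoffs = clf.manifest.get("cutoffs")
    return _predict_records(
        clf, scaler, region, cutoffs, wt_sequence, specs, smiles_by_drug, pairs
    )
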