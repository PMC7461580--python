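"""Classifier configurations, training, prediction, and model persistence.

Three model families are supported on the same feature matrices: the small
deep neural network (two hidden layers, 128 and 32 units), an RBF-kernel SVM
(gamma = 0.001) and a random forest (50 trees, depth ≤ 10).  All expose
4-column class-probability predictions ordered by phenotype code, and all are
saved as a model directory carrying a manifest (config, feature
dimensionality, trim region, scaler parameters, class ordering, seed) so
prediction-time featurization can be replayed verbatim.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .curves import PhenotypeLabel
from .descriptors import Standardizer
from .exceptions import DimensionError
from .mutants import TrimRegion
from .nn import MLPNet, TrainingHistory

N_CLASSES = 4


@dataclass(frozen=True)
class DNNConfig:
    """Hyperparameters of the phenotype DNN.

    Defaults follow the selected architecture: 128/32 hidden units, dropout
    0.01 on each hidden layer, batch size 16, ADAM (step size 0.001), early
    stopping after 20 epochs without inner-validation improvement.
    """

    hidden_sizes: tuple[int, int] = (128, 32)
    dropout: float = 0.01
    batch_size: int = 16
    learning_rate: float = 0.001
    max_epochs: int = 500
    early_stop_patience: int = 20
    inner_validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(h > 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class BaselineConfig:
    """Shallow baseline settings: RBF SVM (gamma 0.001) or RF (50 × depth 10)."""

    model_kind: str = "rf"
    svm_gamma: float = 0.001
    svm_c: float = 1.0
    rf_estimators: int = 50
    rf_max_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("svm", "rf"):
            raise ValueError(f"model_kind must be 'svm' or 'rf', got {self.model_kind!r}")
        if self.svm_gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.rf_estimators < 1:
            raise ValueError("need at least one tree")


@dataclass
class TrainedClassifier:
    """A fitted model plus the manifest needed to reproduce its inputs."""

    kind: str  # "dnn" | "svm" | "rf"
    model: object
    classes_: np.ndarray  # class codes seen at fit time
    manifest: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.manifest["n_features"])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)


def _check_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise DimensionError(f"feature/label shape mismatch: {X.shape} vs {y.shape}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    return X, y


def train_dnn(
    X: np.ndarray, y: np.ndarray, config: DNNConfig | None = None
) -> tuple[TrainedClassifier, TrainingHistory]:
    """Train the phenotype DNN and return it with its training history."""
    config = config or DNNConfig()
    X, y = _check_training_data(X, y)
    net = MLPNet(
        n_classes=N_CLASSES,
        hidden_sizes=config.hidden_sizes,
        dropout=config.dropout,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.early_stop_patience,
        validation_fraction=config.inner_validation_fraction,
        seed=config.seed,
    )
    net.fit(X, y)
    clf = TrainedClassifier(
        kind="dnn",
        model=net,
        classes_=np.arange(N_CLASSES),
        manifest={
            "kind": "dnn",
            "config": dataclasses.asdict(config),
            "n_features": X.shape[1],
            "class_codes": list(range(N_CLASSES)),
            "seed": config.seed,
        },
    )
    return clf, net.history_


def train_baseline(
    X: np.ndarray, y: np.ndarray, config: BaselineConfig | None = None
) -> TrainedClassifier:
    """Train an SVM or random-forest baseline with probability outputs."""
    config = config or BaselineConfig()
    X, y = _check_training_data(X, y)
    if config.model_kind == "svm":
        model = SVC(
            kernel="rbf",
            gamma=config.svm_gamma,
            C=config.svm_c,
            probability=True,
            random_state=config.seed,
        )
    else:
        model = RandomForestClassifier(
            n_estimators=config.rf_estimators,
            max_depth=config.rf_max_depth,
            random_state=config.seed,
        )
    model.fit(X, y)
    return TrainedClassifier(
        kind=config.model_kind,
        model=model,
        classes_=np.asarray(model.classes_, dtype=int),
        manifest={
            "kind": config.model_kind,
            "config": dataclasses.asdict(config),
            "n_features": X.shape[1],
            "class_codes": list(range(N_CLASSES)),
            "seed": config.seed,
        },
    )


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix with 4 columns ordered by phenotype code.

    Classes absent at fit time receive probability 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != clf.n_features:
        raise DimensionError(
            f"model expects {clf.n_features} features, got matrix of shape {X.shape}"
        )
    raw = clf.model.predict_proba(X)
    if raw.shape[1] == N_CLASSES and clf.kind == "dnn":
        return raw
    out = np.zeros((len(X), N_CLASSES))
    for col, code in enumerate(clf.classes_):
        out[:, int(code)] = raw[:, col]
    return out


def predict_label(
    proba: np.ndarray, cutoffs: Sequence[float] | None = None
) -> np.ndarray:
    """Turn class probabilities into labels.

    Without cutoffs: plain argmax (lowest class code wins ties).  With a
    per-class cutoff set: classes whose score reaches their cutoff "pass";
    among passing classes the highest score wins (ties toward the lower
    code); if no class passes, fall back to the global argmax.  With all
    cutoffs at 0 the rule reduces to argmax.
    """
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[1] != N_CLASSES:
        raise DimensionError(f"probability matrix must have {N_CLASSES} columns")
    if cutoffs is None:
        return proba.argmax(axis=1)
    cut = np.asarray(list(cutoffs), dtype=float)
    if cut.shape != (N_CLASSES,) or ((cut < 0) | (cut > 1)).any():
        raise ValueError(f"cutoffs must be {N_CLASSES} values in [0, 1], got {cutoffs}")
    labels = np.empty(len(proba), dtype=int)
    for i, row in enumerate(proba):
        passing = row >= cut
        labels[i] = int((row * passing).argmax()) if passing.any() else int(row.argmax())
    return labels


# -- persistence -------------------------------------------------------------


def save_classifier(
    clf: TrainedClassifier,
    model_dir: str | Path,
    scaler: Standardizer | None = None,
    region: TrimRegion | None = None,
    extra: Mapping | None = None,
) -> Path:
    """Save a model directory: manifest.json plus a weights/params file."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(clf.manifest)
    manifest["classes_seen"] = [int(c) for c in clf.classes_]
    if scaler is not None:
        manifest["scaler"] = scaler.to_dict()
    if region is not None:
        manifest["trim_region"] = {"start": region.start, "end": region.end}
    if extra:
        manifest.update(extra)
    (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if clf.kind == "dnn":
        np.savez(model_dir / "weights.npz", **clf.model.get_params_arrays())
    else:
        (model_dir / "model.pkl").write_bytes(pickle.dumps(clf.model))
    return model_dir


def load_classifier(
    model_dir: str | Path,
) -> tuple[TrainedClassifier, Standardizer | None, TrimRegion | None]:
    """Load a model directory saved by :func:`save_classifier`."""
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    kind = manifest["kind"]
    if kind == "dnn":
        cfg = DNNConfig(**{**manifest["config"], "hidden_sizes": tuple(manifest["config"]["hidden_sizes"])})
        net = MLPNet(
            n_classes=N_CLASSES,
            hidden_sizes=cfg.hidden_sizes,
            dropout=cfg.dropout,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            max_epochs=cfg.max_epochs,
            patience=cfg.early_stop_patience,
            validation_fraction=cfg.inner_validation_fraction,
            seed=cfg.seed,
        )
        with np.load(model_dir / "weights.npz") as arrays:
            net.set_params_arrays(dict(arrays), manifest["n_features"])
        model: object = net
        classes = np.arange(N_CLASSES)
    else:
        model = pickle.loads((model_dir / "model.pkl").read_bytes())
        classes = np.asarray(manifest.get("classes_seen", list(range(N_CLASSES))), dtype=int)
    clf = TrainedClassifier(kind=kind, model=model, classes_=classes, manifest=manifest)
    scaler = Standardizer.from_dict(manifest["scaler"]) if "scaler" in manifest else None
    region = None
    if "trim_region" in manifest:
        region = TrimRegion(manifest["trim_region"]["start"], manifest["trim_region"]["end"])
    return clf, scaler, region
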