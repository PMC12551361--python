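"""Multilayer-perceptron robustness check for the dementia classifier.

A deliberately traditional architecture: exactly one hidden layer with
rectified-linear activation, softmax output over the three cognitive
status classes, cross-entropy loss, plain mini-batch SGD with a fixed
learning rate, and early stopping on a held-out validation fraction with
the best-epoch weights restored.  Validity is defined exactly as for the
ordered-probit classifier, so the two backends are directly comparable.

The estimator is scikit-learn's ``MLPClassifier`` (with features
standardized to mean 0, SD 1 on the training split) behind the same
interface as the main classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from dementia_cohorts.classify import (
    ValidationReport,
    build_features,
    compute_validity,
    feature_matrix,
)
from dementia_cohorts.simulate import DEMENTIA, GoldStandard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training schedule of the robustness classifier."""

    hidden_units: int = 32
    activation: str = "relu"  # fixed; "identity" allowed only for diagnostics
    validation_fraction: float = 0.2
    patience_epochs: int = 30
    max_epochs: int = 400
    learning_rate: float = 0.03
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive (exactly one hidden layer)")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation is ReLU (identity only for the linear-limit check)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs <= 0 or self.patience_epochs < 0:
            raise ValueError("max_epochs must be positive and patience_epochs >= 0")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")


@dataclass
class TrainedMLP:
    """Fitted network plus its input standardization."""

    spec: MLPSpec
    scaler: StandardScaler
    net: MLPClassifier
    feature_names: tuple[str, ...]
    respondent_kind: str = "self"

    @property
    def n_epochs(self) -> int:
        return int(self.net.n_iter_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, columns in ``net.classes_`` order."""
        X = self.scaler.transform(np.asarray(X, dtype=float))
        return self.net.predict_proba(X)

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        X = self.scaler.transform(np.asarray(X, dtype=float))
        return self.net.predict(X)

    def serialize(self) -> dict:
        """Layer shapes and weights as plain lists (structured-text ready)."""
        return {
            "feature_names": list(self.feature_names),
            "classes": [int(c) for c in self.net.classes_],
            "layers": [list(w.shape) for w in self.net.coefs_],
            "weights": [w.tolist() for w in self.net.coefs_],
            "biases": [b.tolist() for b in self.net.intercepts_],
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
        }


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec = MLPSpec(),
    feature_names: tuple[str, ...] | None = None,
    respondent_kind: str = "self",
) -> TrainedMLP:
    """Train the one-hidden-layer network with early stopping.

    Training halts once validation loss has failed to improve for
    ``patience_epochs`` consecutive epochs (0 → the first non-improving
    epoch) or at ``max_epochs``; the best-validation-epoch weights are
    restored.  Reproducible under a fixed spec seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")
    scaler = StandardScaler().fit(X)
    net = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation=spec.activation,
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=spec.learning_rate,
        momentum=0.0,
        nesterovs_momentum=False,
        batch_size=min(spec.batch_size, len(y)),
        max_iter=spec.max_epochs,
        early_stopping=True,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=max(1, spec.patience_epochs),
        random_state=spec.seed,
        alpha=1e-4,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(scaler.transform(X), y)
    if not np.isfinite(net.loss_):
        raise FloatingPointError(
            f"non-finite loss at epoch {net.n_iter_} "
            f"(learning_rate={spec.learning_rate}); reduce the learning rate"
        )
    names = tuple(feature_names) if feature_names else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    return TrainedMLP(
        spec=spec, scaler=scaler, net=net, feature_names=names,
        respondent_kind=respondent_kind,
    )


def evaluate_mlp(
    model: TrainedMLP,
    X: np.ndarray,
    gold: np.ndarray,
    kinds=None,
) -> ValidationReport:
    """Validity of the network's dementia calls against gold labels.

    Same definition as the main classifier: percent of cases whose
    predicted dementia status (argmax class collapsed to dementia /
    no dementia) equals the gold status.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else None} "
            f"!= model dimension {len(model.feature_names)}"
        )
    if len(gold) == 0:
        raise ValueError("empty evaluation set")
    pred = (model.predict_class(X) == DEMENTIA).astype(int)
    return compute_validity(pred, gold, kinds=kinds)


def classify_panel_mlp(
    records: pd.DataFrame,
    gold: GoldStandard,
    spec: MLPSpec = MLPSpec(),
) -> tuple[pd.DataFrame, dict[str, TrainedMLP], ValidationReport]:
    """End-to-end MLP classification mirroring the ordered-probit pipeline.

    Separate networks per respondent kind (self vs proxy), trained on the
    gold calibration half, evaluated on the held-out half; returns the
    panel with ``dementia_hat_mlp``, the per-kind models, and the report.
    """
    features = {kind: build_features(records, kind) for kind in ("self", "proxy")}
    train_labels = gold.split("train")
    models: dict[str, TrainedMLP] = {}
    scored_parts = []
    for kind, feats in features.items():
        lab = train_labels.merge(feats, on=["person_id", "wave"], how="inner")
        if lab.empty:
            logger.warning("no gold calibration cases of kind %r for MLP", kind)
            continue
        X, names = feature_matrix(lab.drop(columns=["true_class"]))
        model = train_mlp(
            X,
            lab["true_class"].to_numpy(),
            spec=spec,
            feature_names=names,
            respondent_kind=kind,
        )
        models[kind] = model
        X_all, _ = feature_matrix(feats, names)
        part = feats[["person_id", "wave"]].copy()
        part["kind"] = kind
        part["dementia_hat_mlp"] = (model.predict_class(X_all) == DEMENTIA).astype(int)
        scored_parts.append(part)
    scored = pd.concat(scored_parts, ignore_index=True)
    out = records.merge(scored, on=["person_id", "wave"], how="left")
    out.attrs.update(records.attrs)

    val = gold.split("validation").merge(scored, on=["person_id", "wave"], how="inner")
    report = compute_validity(val["dementia_hat_mlp"], val["true_class"], kinds=val["kind"])
    logger.info("MLP validity %.1f%% on %d held-out gold cases", report.accuracy, report.n)
    return out, models, report
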