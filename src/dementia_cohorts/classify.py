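"""Dementia status imputation from survey cognition data.

Separate ordered-probit models are fitted for self-respondents (scored on
the telephone cognitive battery: word recall, serial sevens, orientation)
and proxy respondents (scored on the informant questionnaire), using
demographics, ADL/IADL limitation counts, current scores, and between-wave
score changes as predictors.  The models are trained on a gold-standard
calibration half of the clinically adjudicated subsample, a dementia
cutoff on the predicted dementia probability is tuned on the same half,
and validity — the percentage of respondents whose predicted status
matches the clinical status — is reported on the held-out half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from dementia_cohorts.ordered_probit import (
    OrderedProbitModel,
    SeparationError,
    class_probabilities,
    fit_ordered_probit,
)
from dementia_cohorts.report import percentage
from dementia_cohorts.simulate import DEMENTIA, GoldStandard

logger = logging.getLogger(__name__)

#: Score-type features whose between-wave changes enter the models.
SELF_SCORES = ("word_recall", "serial7", "orientation")
PROXY_SCORES = ("informant_score",)

#: Base (non-change) features per respondent kind.
BASE_FEATURES: Mapping[str, tuple[str, ...]] = {
    "self": ("age", "female", "education_years", "adl_count", "iadl_count") + SELF_SCORES,
    "proxy": ("age", "female", "education_years", "adl_count", "iadl_count") + PROXY_SCORES,
}


@dataclass
class ClassProbabilities:
    """Predicted 3-class probabilities for one person-wave."""

    p_dementia: float
    p_cind: float
    p_normal: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_dementia, self.p_cind, self.p_normal])


@dataclass
class ValidationReport:
    """Agreement of predicted dementia status with the gold standard."""

    accuracy: float  # percent, one decimal
    confusion: pd.DataFrame  # rows = gold status, columns = predicted
    n: int
    by_kind: dict[str, float] = field(default_factory=dict)


@dataclass
class ClassifierResult:
    """End-to-end classification output for one panel."""

    records: pd.DataFrame  # panel with p_dementia and dementia_hat columns
    models: dict[str, OrderedProbitModel]
    rule: str
    cutoff: float | None
    report: ValidationReport


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def build_features(records: pd.DataFrame, kind: Literal["self", "proxy"]) -> pd.DataFrame:
    """One feature row per person-wave of the given respondent kind.

    Change features are current minus the same person's most recent prior
    wave of the same kind, zero at a person's first observed wave (with a
    companion ``first_wave`` indicator).  Missing values are imputed by the
    within-kind sample mean with a companion missing-indicator column.
    """
    if kind not in BASE_FEATURES:
        raise ValueError(f"kind must be 'self' or 'proxy', got {kind!r}")
    sel = records[records["proxy"] == (kind == "proxy")].copy()
    sel = sel.sort_values(["person_id", "wave"], kind="stable")
    if "age" not in sel.columns:
        sel["age"] = sel["interview_year"].astype(int) - sel["birth_year"].astype(int)
    sel["female"] = (sel["gender"] == "female").astype(float)

    base = BASE_FEATURES[kind]
    unknown = [f for f in base if f not in sel.columns]
    if unknown:
        raise KeyError(f"panel lacks feature columns {unknown}")

    out = sel[["person_id", "wave"]].reset_index(drop=True)
    score_cols = SELF_SCORES if kind == "self" else PROXY_SCORES
    grouped = sel.groupby("person_id", sort=False)

    for name in base:
        col = pd.to_numeric(sel[name], errors="coerce")
        miss = col.isna()
        filled = col.fillna(col.mean() if miss.any() and not miss.all() else 0.0)
        out[name] = filled.to_numpy()
        if miss.any():
            out[f"{name}_missing"] = miss.to_numpy().astype(float)
        if name in score_cols:
            prev = grouped[name].shift(1)
            change = (col - pd.to_numeric(prev, errors="coerce")).to_numpy()
            out[f"{name}_change"] = np.nan_to_num(change, nan=0.0)

    first = grouped.cumcount().to_numpy() == 0
    out["first_wave"] = first.astype(float)
    return out


def feature_matrix(
    features: pd.DataFrame, names: Sequence[str] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Numeric design (with intercept) from a feature frame.

    Without ``names``, all non-identifier columns with any variation are
    used; with ``names``, exactly those columns in that order (for
    prediction with a fitted model).
    """
    if names is None:
        cols = [
            c
            for c in features.columns
            if c not in ("person_id", "wave") and features[c].nunique() > 1
        ]
        names = ("const", *cols)
    cols = [c for c in names if c != "const"]
    X = np.column_stack(
        [np.ones(len(features))] + [features[c].to_numpy(dtype=float) for c in cols]
    )
    return X, tuple(names)


# ---------------------------------------------------------------------------
# prediction & calibration
# ---------------------------------------------------------------------------

def predict_probs(
    model: OrderedProbitModel, x: np.ndarray | pd.DataFrame
) -> ClassProbabilities | np.ndarray:
    """3-class probabilities; a single vector yields a ClassProbabilities."""
    if isinstance(x, pd.DataFrame):
        X, _ = feature_matrix(x, model.feature_names)
        return class_probabilities(model, X)
    x = np.asarray(x, dtype=float)
    probs = class_probabilities(model, x)
    if x.ndim == 1:
        return ClassProbabilities(*probs[0])
    return probs


CUTOFF_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 3)


def select_cutoff(p_dementia: np.ndarray, gold_binary: np.ndarray) -> float:
    """Grid-search the dementia-probability threshold maximizing accuracy.

    Step 0.005; ties broken toward the lower threshold; a case is
    classified as dementia when p_dementia ≥ threshold.
    """
    p = np.asarray(p_dementia, dtype=float)
    gold = np.asarray(gold_binary, dtype=int)
    if p.size == 0:
        raise ValueError("empty gold calibration split")
    acc = np.array([np.mean((p >= t).astype(int) == gold) for t in CUTOFF_GRID])
    return float(CUTOFF_GRID[int(np.argmax(acc))])


def calibrate_and_classify(
    models: Mapping[str, OrderedProbitModel],
    features: Mapping[str, pd.DataFrame],
    gold_train: pd.DataFrame | None = None,
    rule: Literal["argmax", "cutoff"] = "cutoff",
) -> tuple[pd.DataFrame, float | None]:
    """Binary dementia classification for every person-wave.

    ``argmax`` assigns dementia when p_dementia is the largest of the three
    class probabilities; ``cutoff`` (the default) tunes a probability
    threshold on the gold calibration split.  Returns a frame with columns
    person_id, wave, p_dementia, dementia_hat, kind — plus the cutoff used.
    """
    frames = []
    for kind, model in models.items():
        feats = features[kind]
        if feats.empty:
            continue
        probs = predict_probs(model, feats)
        part = feats[["person_id", "wave"]].copy()
        part["kind"] = kind
        part["p_dementia"] = probs[:, 0]
        part["p_cind"] = probs[:, 1]
        part["p_normal"] = probs[:, 2]
        frames.append(part)
    if not frames:
        return pd.DataFrame(
            columns=["person_id", "wave", "kind", "p_dementia", "p_cind", "p_normal", "dementia_hat"]
        ), None
    scored = pd.concat(frames, ignore_index=True)

    cutoff: float | None = None
    if rule == "argmax":
        scored["dementia_hat"] = (
            (scored["p_dementia"] >= scored[["p_cind", "p_normal"]].max(axis=1))
        ).astype(int)
    elif rule == "cutoff":
        if gold_train is None or gold_train.empty:
            raise ValueError("cutoff rule needs a non-empty gold calibration split")
        cal = gold_train.merge(scored, on=["person_id", "wave"], how="inner")
        cutoff = select_cutoff(
            cal["p_dementia"].to_numpy(), (cal["true_class"] == DEMENTIA).to_numpy()
        )
        logger.info("calibrated dementia cutoff: %.3f on %d gold cases", cutoff, len(cal))
        scored["dementia_hat"] = (scored["p_dementia"] >= cutoff).astype(int)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return scored, cutoff


def compute_validity(
    predicted: Sequence[int],
    gold: Sequence[int],
    kinds: Sequence[str] | None = None,
) -> ValidationReport:
    """Percent agreement of predicted with gold dementia status.

    ``gold`` may be 3-class (collapsed to dementia / no dementia) or
    already binary.  Accuracy is reported in percent to one decimal.
    """
    pred = np.asarray(predicted, dtype=int)
    gold = np.asarray(gold, dtype=int)
    if pred.size == 0:
        raise ValueError("empty validation split")
    if pred.size != gold.size:
        raise ValueError("predicted and gold lengths differ")
    gold_bin = (
        (gold == DEMENTIA).astype(int) if set(np.unique(gold)) - {0, 1} else gold
    )
    n = pred.size
    agree = int((pred == gold_bin).sum())
    confusion = pd.crosstab(
        pd.Series(gold_bin, name="gold"),
        pd.Series(pred, name="predicted"),
        dropna=False,
    ).reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    by_kind: dict[str, float] = {}
    if kinds is not None:
        kinds = np.asarray(kinds)
        for kind in np.unique(kinds):
            m = kinds == kind
            if m.any():
                by_kind[str(kind)] = percentage(int((pred[m] == gold_bin[m]).sum()), int(m.sum()))
    return ValidationReport(
        accuracy=percentage(agree, n), confusion=confusion, n=n, by_kind=by_kind
    )


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def classify_panel(
    records: pd.DataFrame,
    gold: GoldStandard,
    rule: Literal["argmax", "cutoff"] = "cutoff",
    fit_seed: int = 0,
) -> ClassifierResult:
    """Train per-kind models on the gold calibration half, classify the panel.

    The gold subsample is split by person into disjoint calibration and
    validation halves; reported validity is therefore out of sample.
    """
    features = {kind: build_features(records, kind) for kind in ("self", "proxy")}
    train_labels = gold.split("train")
    val_labels = gold.split("validation")

    models: dict[str, OrderedProbitModel] = {}
    for kind, feats in features.items():
        lab = train_labels.merge(feats, on=["person_id", "wave"], how="inner")
        if lab.empty:
            logger.warning("no gold calibration cases of kind %r; skipping model", kind)
            continue
        feat_cols = lab.drop(columns=["true_class"])
        X, names = feature_matrix(feat_cols)
        labels = lab["true_class"].to_numpy()
        try:
            models[kind] = fit_ordered_probit(
                X, labels, feature_names=names, respondent_kind=kind, seed=fit_seed
            )
        except SeparationError:
            # small calibration samples can be quasi-separated; refit with a
            # weak L2 guard on the slopes and log the fallback
            logger.warning(
                "quasi-separation in %r calibration sample (n=%d); "
                "refitting with ridge=0.01",
                kind,
                len(labels),
            )
            models[kind] = fit_ordered_probit(
                X, labels, feature_names=names, respondent_kind=kind,
                seed=fit_seed, ridge=0.01,
            )

    scored, cutoff = calibrate_and_classify(
        models, features, gold_train=train_labels if rule == "cutoff" else None, rule=rule
    )
    out = records.merge(
        scored[["person_id", "wave", "kind", "p_dementia", "dementia_hat"]],
        on=["person_id", "wave"],
        how="left",
    )
    out.attrs.update(records.attrs)

    val = val_labels.merge(scored, on=["person_id", "wave"], how="inner")
    report = compute_validity(
        val["dementia_hat"], val["true_class"], kinds=val["kind"]
    )
    logger.info(
        "classifier validity %.1f%% on %d held-out gold cases (rule=%s, cutoff=%s)",
        report.accuracy,
        report.n,
        rule,
        cutoff,
    )
    return ClassifierResult(
        records=out, models=models, rule=rule, cutoff=cutoff, report=report
    )
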