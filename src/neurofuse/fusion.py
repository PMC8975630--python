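"""Two-level hybrid fusion and its leave-one-out evaluation harness.

Level 1 fuses the behavioral modalities at the feature level: the facial-
expression vector f2 and the eye-fixation vector f3 are concatenated and
classified by a base classifier, giving the behavioral subdecision d2.  The
physiological EEG vector f1 is classified independently, giving d1.  Level 2
fuses (d1, d2) at the decision level with the attribute-weighted naive
Bayes, yielding the final decision.

Evaluation is leave-one-out cross-validation with a strict no-leakage
contract: in each fold the gaze K-means, the EEG t-test screen (in screened
mode), the base classifiers and the naive-Bayes weights are all fitted on
the n-1 training subjects only.  The decision table that trains the weighted
naive Bayes is built from *inner* leave-one-out subdecisions over the
training fold — resubstitution subdecisions would be near-perfect and would
push the learned weights toward degenerate confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import eeg as eeg_mod
from . import expr as expr_mod
from . import gaze as gaze_mod
from . import wnb as wnb_mod
from .types import CLASSES, Cohort

__all__ = ["FusionConfig", "EvaluationReport", "make_classifier",
           "level1_behavioral", "level1_physiological", "level2_fuse",
           "loocv", "confusion_report", "confusion_graph"]

MODALITIES = ("hybrid", "eeg", "gaze", "expr", "behavioral")


@dataclass
class FusionConfig:
    """Configuration of the fusion pipeline and its base classifier."""

    base_classifier: str = "rf"          # rf | svm | knn
    rf_n_estimators: int = 500
    svm_c: float = 1.0
    knn_k: int = 5
    gaze_k: int = 8                      # AOI count; 8/12/16/20 are typical
    gaze_n_init: int = 10
    expr_window: int = 40
    eeg_mode: str = "fixed12"            # fixed12 | screened
    eeg_alpha: float = 0.05
    epoch_s: float = 2.0
    amp_thresh: float = 100.0
    wnb_smoothing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_classifier not in ("rf", "svm", "knn"):
            raise ValueError(f"base_classifier: expected rf, svm or knn, "
                             f"got {self.base_classifier!r}")
        if self.eeg_mode not in ("fixed12", "screened"):
            raise ValueError(f"eeg_mode: expected fixed12 or screened, got "
                             f"{self.eeg_mode!r}")


def make_classifier(config: FusionConfig, seed: int):
    """A fresh base classifier; distance-based ones get feature scaling."""
    if config.base_classifier == "rf":
        return RandomForestClassifier(n_estimators=config.rf_n_estimators,
                                      random_state=seed)
    if config.base_classifier == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(C=config.svm_c, kernel="rbf"))
    return make_pipeline(StandardScaler(),
                         KNeighborsClassifier(n_neighbors=config.knn_k))


def _fold_seed(config: FusionConfig, fold: int) -> int:
    return (config.seed * 1_000_003 + fold * 7919) % (2 ** 31)


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if not a.index.equals(b.index):
        offenders = sorted(set(a.index).symmetric_difference(b.index))
        raise ValueError(f"subject mismatch between feature blocks: "
                         f"{offenders or 'same ids, different order'}")


def level1_behavioral(expr_features: pd.DataFrame,
                      gaze_features: pd.DataFrame,
                      labels: Sequence[str], config: FusionConfig
                      ) -> pd.Series:
    """Feature-fuse f2 (expression) with f3 (gaze), train the base
    classifier, and return per-subject categorical subdecisions."""
    _check_aligned(expr_features, gaze_features)
    X = pd.concat([expr_features, gaze_features], axis=1).to_numpy()
    clf = make_classifier(config, _fold_seed(config, 0))
    clf.fit(X, np.asarray(labels))
    return pd.Series(clf.predict(X), index=expr_features.index,
                     name="d2")


def level1_physiological(eeg_features: pd.DataFrame, labels: Sequence[str],
                         config: FusionConfig) -> pd.Series:
    """Train the base classifier on EEG features; per-subject subdecisions."""
    clf = make_classifier(config, _fold_seed(config, 0))
    clf.fit(eeg_features.to_numpy(), np.asarray(labels))
    return pd.Series(clf.predict(eeg_features.to_numpy()),
                     index=eeg_features.index, name="d1")


def level2_fuse(d1: Sequence[str], d2: Sequence[str], labels: Sequence[str],
                smoothing: float = 1.0
                ) -> tuple[list[str], wnb_mod.WeightedNaiveBayes]:
    """Decision-fuse two subdecision vectors with weighted naive Bayes.

    Builds the 2-attribute decision table (d1, d2, label), fits the model
    and returns its predictions on the same rows plus the fitted model.
    """
    rows = list(zip(d1, d2))
    if len(rows) != len(labels):
        raise ValueError("subdecisions and labels are not aligned")
    model = wnb_mod.fit(rows, list(labels), smoothing=smoothing)
    return model.predict_many(rows), model


def _bare_classifier(config: FusionConfig, seed: int):
    """Base classifier without the scaling step (for pre-scaled input)."""
    if config.base_classifier == "rf":
        return RandomForestClassifier(n_estimators=config.rf_n_estimators,
                                      random_state=seed)
    if config.base_classifier == "svm":
        return SVC(C=config.svm_c, kernel="rbf")
    return KNeighborsClassifier(n_neighbors=config.knn_k)


def _inner_loo_subdecisions(X: np.ndarray, y: np.ndarray,
                            config: FusionConfig, seed: int) -> list[str]:
    """Leave-one-out subdecisions within a training fold: subject t is
    predicted by a classifier trained on the fold minus t.

    For the distance-based classifiers the features are standardised once
    with the training fold's statistics (the fold is the training set; only
    the outer held-out subject must stay unseen).
    """
    if config.base_classifier in ("svm", "knn"):
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd
    preds = []
    idx = np.arange(len(y))
    for t in idx:
        clf = _bare_classifier(config, (seed + 31 * int(t)) % (2 ** 31))
        mask = idx != t
        clf.fit(X[mask], y[mask])
        preds.append(clf.predict(X[t:t + 1])[0])
    return preds


# --------------------------------------------------------------- reporting

def confusion_report(predictions: Sequence[str], labels: Sequence[str]
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Column-normalised confusion matrix and confusion-graph edges.

    Entry (i, j) is the percentage of true-class-j subjects predicted as
    class i, so each column sums to 100.  Edges are the off-diagonal
    percentages, keyed ``"ASD->TD"`` (true ASD called TD) etc.
    """
    predictions, labels = list(predictions), list(labels)
    if not predictions:
        raise ValueError("predictions: empty input")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels are not aligned")
    mat = pd.DataFrame(0.0, index=list(CLASSES), columns=list(CLASSES))
    for true in CLASSES:
        n_true = sum(1 for lab in labels if lab == true)
        if n_true == 0:
            continue
        for pred in CLASSES:
            n = sum(1 for p, lab in zip(predictions, labels)
                    if lab == true and p == pred)
            mat.loc[pred, true] = 100.0 * n / n_true
    edges = {f"{true}->{pred}": float(mat.loc[pred, true])
             for true in CLASSES for pred in CLASSES if pred != true}
    return mat, edges


def confusion_graph(reports: dict[str, "EvaluationReport"]
                    ) -> dict[str, dict[str, float]]:
    """Misclassification edges per modality, for complementarity analysis
    across modality pairs (which class each modality tends to confuse)."""
    return {name: rep.edges for name, rep in reports.items()}


@dataclass
class EvaluationReport:
    """Held-out LOOCV predictions and derived summaries for one run."""

    modality: str
    subject_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    accuracy: float                       # percent
    confusion: pd.DataFrame               # column-normalised percent
    edges: dict[str, float]
    branch_predictions: dict[str, list[str]] = field(default_factory=dict)
    config: FusionConfig | None = None

    def branch_accuracy(self, branch: str) -> float:
        preds = self.branch_predictions[branch]
        ok = sum(p == t for p, t in zip(preds, self.y_true))
        return 100.0 * ok / len(self.y_true)

    def to_json(self) -> str:
        return json.dumps({
            "modality": self.modality,
            "subject_ids": self.subject_ids,
            "y_true": self.y_true,
            "y_pred": self.y_pred,
            "accuracy": self.accuracy,
            "confusion": {c: self.confusion[c].tolist()
                          for c in self.confusion.columns},
            "edges": self.edges,
            "branch_predictions": self.branch_predictions,
        }, sort_keys=True)


# -------------------------------------------------------------------- LOOCV

def _feature_blocks(cohort: Cohort, config: FusionConfig, fold: int,
                    train_ids: set[str] | None,
                    expr_df: pd.DataFrame,
                    eeg_tables: list[pd.DataFrame],
                    ) -> dict[str, pd.DataFrame]:
    """Per-fold feature blocks; label- or pool-dependent fits (gaze
    K-means, EEG screen) see only the training subjects."""
    fixations = [s.fixations for s in cohort.subjects]
    recordings = [s.eeg for s in cohort.subjects]
    gaze_df, _ = gaze_mod.gaze_feature_table(
        fixations, K=config.gaze_k, seed=_fold_seed(config, fold),
        n_init=config.gaze_n_init, train_ids=train_ids)
    eeg_df = eeg_mod.eeg_feature_table(
        recordings, mode=config.eeg_mode, labels=cohort.labels,
        train_ids=train_ids, alpha=config.eeg_alpha, tables=eeg_tables)
    return {"eeg": eeg_df, "expr": expr_df, "gaze": gaze_df,
            "behavioral": pd.concat([expr_df, gaze_df], axis=1)}


def loocv(cohort: Cohort, config: FusionConfig | None = None,
          modality: str = "hybrid") -> EvaluationReport:
    """Leave-one-out evaluation of a single modality or the hybrid fusion.

    ``modality`` is one of ``eeg``, ``gaze``, ``expr``, ``behavioral``
    (expression + gaze feature fusion) or ``hybrid`` (the full two-level
    framework).  For ``hybrid`` the report also carries the held-out
    subdecisions of the physiological (``d1``) and behavioral (``d2``)
    branches, which are themselves valid single-branch LOOCV predictions.
    """
    config = config or FusionConfig()
    if modality not in MODALITIES:
        raise ValueError(f"modality: expected one of {MODALITIES}, got "
                         f"{modality!r}")
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort: need at least 2 subjects")
    labels = np.asarray(cohort.labels)
    ids = cohort.subject_ids
    if len(set(labels)) < 2:
        raise ValueError("cohort: both classes must be present")

    # label-free per-subject precomputation, shared across folds
    expr_df = expr_mod.expr_feature_table(
        [s.expressions for s in cohort.subjects], window=config.expr_window)
    eeg_tables = [eeg_mod.region_band_features(
        s.eeg, epoch_s=config.epoch_s, amp_thresh=config.amp_thresh)
        for s in cohort.subjects]

    y_pred: list[str] = []
    d1_out: list[str] = []
    d2_out: list[str] = []
    for fold in range(n):
        train_mask = np.arange(n) != fold
        if len(set(labels[train_mask])) < 2:
            raise ValueError(f"fold {fold}: training set has a single class")
        train_ids = {ids[i] for i in range(n) if train_mask[i]}
        blocks = _feature_blocks(cohort, config, fold, train_ids,
                                 expr_df, eeg_tables)
        y_tr = labels[train_mask]
        seed = _fold_seed(config, fold)
        if modality == "hybrid":
            X1 = blocks["eeg"].to_numpy()
            X2 = blocks["behavioral"].to_numpy()
            d1_tr = _inner_loo_subdecisions(X1[train_mask], y_tr, config,
                                            seed)
            d2_tr = _inner_loo_subdecisions(X2[train_mask], y_tr, config,
                                            seed + 1)
            model = wnb_mod.fit(list(zip(d1_tr, d2_tr)), list(y_tr),
                                smoothing=config.wnb_smoothing)
            clf1 = make_classifier(config, seed + 2)
            clf1.fit(X1[train_mask], y_tr)
            clf2 = make_classifier(config, seed + 3)
            clf2.fit(X2[train_mask], y_tr)
            d1_t = clf1.predict(X1[fold:fold + 1])[0]
            d2_t = clf2.predict(X2[fold:fold + 1])[0]
            d1_out.append(d1_t)
            d2_out.append(d2_t)
            y_pred.append(model.predict((d1_t, d2_t)))
        else:
            X = blocks[modality].to_numpy()
            clf = make_classifier(config, seed)
            clf.fit(X[train_mask], y_tr)
            y_pred.append(clf.predict(X[fold:fold + 1])[0])

    acc = 100.0 * sum(p == t for p, t in zip(y_pred, labels)) / n
    mat, edges = confusion_report(y_pred, list(labels))
    branch = {}
    if modality == "hybrid":
        branch = {"d1": d1_out, "d2": d2_out}
    return EvaluationReport(modality=modality, subject_ids=list(ids),
                            y_true=list(labels), y_pred=y_pred,
                            accuracy=acc, confusion=mat, edges=edges,
                            branch_predictions=branch, config=config)
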