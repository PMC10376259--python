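"""Leave-one-subject-out clip classification and subject-level voting.

Clip features are classified by an RBF-kernel SVM trained, per fold, on
every other subject's clips (standardized with training-fold statistics
only).  Each held-out subject receives a dementia-vote fraction — the share
of their clips predicted as dementia — and a threshold sweep turns those
fractions into subject decisions, reporting both the accuracy-maximizing
threshold and the (discrete) equal-error-rate operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic import DEMENTIA, HEALTHY

__all__ = [
    "SVMConfig",
    "ClipPredictionSet",
    "ThresholdSweepResult",
    "MetricsReport",
    "loso_clip_predictions",
    "vote",
    "threshold_sweep",
    "compute_metrics",
    "loso_evaluate",
]

_META_COLUMNS = ("subject_id", "session_id", "clip_index", "label")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters. ``gamma='scale'`` is 1/(n_features * var)."""

    C: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass(frozen=True)
class ClipPredictionSet:
    """Held-out clip predictions grouped by subject.

    ``fractions[s]`` is the dementia-vote fraction of subject ``s``;
    ``labels[s]`` the true label; ``clip_predictions[s]`` the per-clip
    predicted labels (strings).
    """

    fractions: dict[str, float]
    labels: dict[str, str]
    clip_predictions: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for subject, p in self.fractions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"vote fraction of {subject!r} outside [0, 1]: {p}")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.fractions)


@dataclass(frozen=True)
class ThresholdSweepResult:
    table: pd.DataFrame = field(repr=False)
    best_threshold: float
    best_accuracy: float
    best_recall: float
    best_precision: float
    eer_threshold: float
    eer_accuracy: float


@dataclass(frozen=True)
class MetricsReport:
    """Standard binary metrics with dementia as the positive class."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    eer_accuracy: float | None = None


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def loso_clip_predictions(
    feature_table: pd.DataFrame, svm_cfg: SVMConfig = SVMConfig()
) -> ClipPredictionSet:
    """One LOSO fold per subject: train on everyone else's clips, predict
    the held-out subject's clips, record the dementia-vote fraction.

    Features are standardized with the training fold's mean and sd, so no
    statistic of the held-out subject leaks into its own fold.
    """
    feature_cols = _feature_columns(feature_table)
    if not feature_cols:
        raise ValueError("feature table has no feature columns")
    subjects = feature_table["subject_id"].unique()
    fractions: dict[str, float] = {}
    labels: dict[str, str] = {}
    clip_preds: dict[str, tuple[str, ...]] = {}
    for subject in sorted(subjects):
        held = feature_table["subject_id"] == subject
        train = feature_table[~held]
        test = feature_table[held]
        train_classes = set(train["label"])
        if len(train_classes) < 2:
            raise ValueError(
                f"fold for subject {subject!r}: training set contains only {train_classes}"
            )
        scaler = StandardScaler().fit(train[feature_cols].to_numpy())
        clf = SVC(C=svm_cfg.C, kernel="rbf", gamma=svm_cfg.gamma)
        clf.fit(scaler.transform(train[feature_cols].to_numpy()), train["label"].to_numpy())
        pred = clf.predict(scaler.transform(test[feature_cols].to_numpy()))
        fractions[subject] = float(np.mean(pred == DEMENTIA))
        subject_labels = set(test["label"])
        if len(subject_labels) != 1:
            raise ValueError(f"subject {subject!r} carries multiple labels")
        labels[subject] = subject_labels.pop()
        clip_preds[subject] = tuple(pred.tolist())
    return ClipPredictionSet(fractions, labels, clip_preds)


def vote(dementia_fraction: float, threshold: float, polarity: str = "dementia") -> str:
    """Subject decision from the dementia-vote fraction.

    Default polarity declares dementia iff the fraction strictly exceeds
    the threshold; ``threshold=0.5`` is majority voting.  The alternative
    ``'healthy'`` polarity declares healthy iff the healthy fraction
    strictly exceeds the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if polarity == "dementia":
        return DEMENTIA if dementia_fraction > threshold else HEALTHY
    if polarity == "healthy":
        return HEALTHY if (1.0 - dementia_fraction) > threshold else DEMENTIA
    raise ValueError(f"unknown polarity {polarity!r}")


def _sweep_candidates(fractions: np.ndarray) -> np.ndarray:
    grid = np.unique(np.concatenate([fractions, [0.0, 1.0]]))
    mids = (grid[:-1] + grid[1:]) / 2.0
    return np.unique(np.concatenate([grid, mids]))


def threshold_sweep(
    prediction_set: ClipPredictionSet, polarity: str = "dementia"
) -> ThresholdSweepResult:
    """Evaluate every decision threshold on the subject vote fractions.

    Candidates are the sorted unique fractions plus {0, 1} and the
    midpoints between consecutive values, which covers every achievable
    decision vector.  Reports the max-accuracy entry and the discrete EER
    entry (argmin |FPR - FNR|), breaking ties toward the smallest
    threshold; the EER accuracy is the mean of the two class-wise
    accuracies at that threshold.
    """
    subjects = prediction_set.subjects
    truth = np.array([prediction_set.labels[s] == DEMENTIA for s in subjects])
    if truth.all() or not truth.any():
        raise ValueError("threshold sweep needs at least one subject of each class")
    fractions = np.array([prediction_set.fractions[s] for s in subjects])
    rows = []
    for t in _sweep_candidates(fractions):
        decided = np.array([vote(p, t, polarity) == DEMENTIA for p in fractions])
        tp = int(np.sum(decided & truth))
        fn = int(np.sum(~decided & truth))
        fp = int(np.sum(decided & ~truth))
        tn = int(np.sum(~decided & ~truth))
        recall = tp / (tp + fn)
        specificity = tn / (tn + fp)
        rows.append(
            {
                "threshold": float(t),
                "accuracy": (tp + tn) / truth.size,
                "recall": recall,
                "precision": tp / (tp + fp) if (tp + fp) else 0.0,
                "fpr": 1.0 - specificity,
                "fnr": 1.0 - recall,
                "balanced_accuracy": (recall + specificity) / 2.0,
            }
        )
    table = pd.DataFrame(rows)
    if polarity == "dementia" and np.any(np.diff(table["recall"].to_numpy()) > 1e-12):
        raise AssertionError("recall must be nonincreasing in the threshold")
    best = table.loc[table["accuracy"].idxmax()]  # idxmax -> first (smallest t) on ties
    eer_gap = (table["fpr"] - table["fnr"]).abs()
    eer = table.loc[eer_gap.idxmin()]
    return ThresholdSweepResult(
        table=table,
        best_threshold=float(best["threshold"]),
        best_accuracy=float(best["accuracy"]),
        best_recall=float(best["recall"]),
        best_precision=float(best["precision"]),
        eer_threshold=float(eer["threshold"]),
        eer_accuracy=float(eer["balanced_accuracy"]),
    )


def compute_metrics(
    decisions: dict[str, str] | pd.Series,
    labels: dict[str, str] | pd.Series,
    eer_accuracy: float | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics with dementia as the positive class.

    An undefined precision (no positive predictions) is reported as 0 with
    a warning; F1 is 0 when precision + recall is 0.
    """
    decisions = dict(decisions)
    labels = dict(labels)
    if not decisions:
        raise ValueError("no decisions to score")
    if set(decisions) != set(labels):
        raise ValueError("decisions and labels must cover the same subjects")
    subjects = sorted(decisions)
    pred = np.array([decisions[s] == DEMENTIA for s in subjects])
    truth = np.array([labels[s] == DEMENTIA for s in subjects])
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    accuracy = (tp + tn) / len(subjects)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no positive predictions: precision undefined, reported as 0", stacklevel=2)
        precision = 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MetricsReport(accuracy, recall, precision, f1, eer_accuracy)


def loso_evaluate(
    feature_table: pd.DataFrame,
    svm_cfg: SVMConfig = SVMConfig(),
    polarity: str = "dementia",
) -> dict:
    """Full subject-level evaluation: LOSO folds, threshold sweep, metrics
    at the accuracy-maximizing threshold, EER accuracy from the sweep."""
    preds = loso_clip_predictions(feature_table, svm_cfg)
    sweep = threshold_sweep(preds, polarity)
    decisions = {
        s: vote(preds.fractions[s], sweep.best_threshold, polarity) for s in preds.subjects
    }
    metrics = compute_metrics(decisions, preds.labels, eer_accuracy=sweep.eer_accuracy)
    return {
        "predictions": preds,
        "sweep": sweep,
        "decisions": decisions,
        "metrics": metrics,
    }
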