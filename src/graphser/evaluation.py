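"""Speaker-independent evaluation.

Motif rows are classified with a Random Forest under leave-one-speaker-out
cross-validation (LOSO-CV): each fold holds out every row of one speaker and
trains on the rest, so no speaker contributes to both sides of a fold.  The
headline score is the unweighted average recall (UAR) — the mean of the
per-class recalls — computed on the confusion matrix pooled over all folds,
because a single fold holds at most one motif row per emotion and per-fold
recalls would be degenerate.  Macro F1 and macro specificity accompany the
UAR, and an ablation helper rescores restricted feature groups (structural
only, statistical only, and each leave-one-feature-out subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, ParameterError
from .features import FEATURE_NAMES, STATISTICAL_FEATURES, STRUCTURAL_FEATURES
from .motif import MOTIF_COLUMNS, moment_columns

logger = logging.getLogger(__name__)


def uar(confusion: np.ndarray) -> float:
    """Unweighted average recall of a (true x predicted) confusion matrix.

    Classes with no true instances are excluded from the mean (and logged).
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or np.any(cm < 0):
        raise ParameterError(f"confusion matrix must be square and nonnegative, got {cm.shape}")
    support = cm.sum(axis=1)
    if not np.any(support > 0):
        raise ParameterError("confusion matrix has no true instances")
    if np.any(support == 0):
        logger.warning("%d class(es) with zero true instances excluded from UAR",
                       int(np.sum(support == 0)))
    present = support > 0
    recalls = np.diag(cm)[present] / support[present]
    return float(recalls.mean())


def _macro_f1(cm: np.ndarray) -> float:
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp, dtype=float), where=denom > 0)
    present = cm.sum(axis=1) > 0
    return float(f1[present].mean())


def _macro_specificity(cm: np.ndarray) -> float:
    total = cm.sum()
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    tn = total - cm.sum(axis=1) - fp
    denom = tn + fp
    spec = np.divide(tn, denom, out=np.zeros_like(tn, dtype=float), where=denom > 0)
    present = cm.sum(axis=1) > 0
    return float(spec[present].mean())


@dataclass
class CVResult:
    """Outcome of one LOSO-CV run."""

    labels: list[str]                      # fixed emotion ordering of the matrix
    folds: list[dict]                      # per-fold speaker, true, pred
    confusion: np.ndarray                  # pooled over folds
    uar: float
    f1_macro: float
    specificity_macro: float
    seed: int
    n_trees: int
    feature_columns: list[str] = field(default_factory=list)

    @property
    def per_fold_accuracy(self) -> list[float]:
        return [float(np.mean(np.asarray(f["true"]) == np.asarray(f["pred"])))
                for f in self.folds]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "folds": self.folds,
            "confusion": self.confusion.tolist(),
            "uar": self.uar,
            "f1_macro": self.f1_macro,
            "specificity_macro": self.specificity_macro,
            "per_fold_accuracy": self.per_fold_accuracy,
            "seed": self.seed,
            "n_trees": self.n_trees,
            "feature_columns": self.feature_columns,
        }


def _resolve_columns(motifs: pd.DataFrame, feature_columns) -> list[str]:
    if feature_columns is None:
        feature_columns = MOTIF_COLUMNS
    missing = [c for c in feature_columns if c not in motifs.columns]
    if missing:
        raise ParameterError(f"motif table is missing columns: {missing}")
    return list(feature_columns)


def losocv(motifs: pd.DataFrame, n_trees: int = 300, seed: int = 0,
           feature_columns=None) -> CVResult:
    """Leave-one-speaker-out Random-Forest classification of motif rows.

    The forest uses ``n_trees`` trees, bootstrap sampling, sqrt(p) candidate
    features per split and unlimited depth; ``seed`` makes the run
    bit-reproducible.  ``feature_columns`` restricts the motif columns used
    (default: all 44).
    """
    if n_trees < 1:
        raise ParameterError("n_trees must be positive")
    columns = _resolve_columns(motifs, feature_columns)
    speakers = sorted(motifs["speaker_id"].unique())
    labels = sorted(motifs["emotion"].unique())
    if len(speakers) < 2:
        raise ConfigurationError("LOSO-CV needs at least 2 speakers")
    if len(labels) < 2:
        raise ConfigurationError("classification needs at least 2 emotion classes")
    label_index = {lab: k for k, lab in enumerate(labels)}
    X = motifs[columns].to_numpy(dtype=np.float64)
    y = motifs["emotion"].to_numpy()
    groups = motifs["speaker_id"].to_numpy()

    confusion = np.zeros((len(labels), len(labels)), dtype=np.int64)
    folds = []
    for speaker in speakers:
        test_mask = groups == speaker
        train_classes = np.unique(y[~test_mask])
        if train_classes.size < 2:
            raise ConfigurationError(
                f"fold holding out {speaker!r}: training set has "
                f"{train_classes.size} class(es), need at least 2"
            )
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", bootstrap=True,
            random_state=seed, n_jobs=1,
        )
        forest.fit(X[~test_mask], y[~test_mask])
        predictions = forest.predict(X[test_mask])
        for truth, pred in zip(y[test_mask], predictions):
            confusion[label_index[truth], label_index[pred]] += 1
        folds.append({"speaker": speaker, "true": list(y[test_mask]),
                      "pred": list(predictions)})
    return CVResult(
        labels=labels, folds=folds, confusion=confusion, uar=uar(confusion),
        f1_macro=_macro_f1(confusion), specificity_macro=_macro_specificity(confusion),
        seed=seed, n_trees=n_trees, feature_columns=columns,
    )


def builtin_groups() -> dict[str, list[str]]:
    """The ablation groups: branch subsets plus leave-one-feature-out."""
    groups = {
        "all": list(FEATURE_NAMES),
        "structural": list(STRUCTURAL_FEATURES),
        "statistical": list(STATISTICAL_FEATURES),
    }
    for feat in FEATURE_NAMES:
        groups[f"minus_{feat}"] = [f for f in FEATURE_NAMES if f != feat]
    return groups


def ablation(motifs: pd.DataFrame, groups: dict[str, list[str]] | None = None,
             n_trees: int = 300, seed: int = 0) -> dict[str, float]:
    """UAR of LOSO-CV restricted to each named feature group.

    Each group is a subset of the 11 utterance features; every feature
    contributes its four moment columns.
    """
    groups = groups if groups is not None else builtin_groups()
    results = {}
    for name, feats in groups.items():
        if not feats:
            raise ParameterError(f"ablation group {name!r} is empty")
        columns = [col for feat in feats for col in moment_columns(feat)]
        results[name] = losocv(motifs, n_trees=n_trees, seed=seed,
                               feature_columns=columns).uar
    return results
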