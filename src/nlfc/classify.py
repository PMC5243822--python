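"""Nested leave-one-out classification with incremental feature counts.

For each held-out subject, features are re-ranked by the cross-group
Kendall statistic on the training subjects only (no leakage of the test
subject into selection), and a linear soft-margin C-SVM is trained on the
top-k features for every k up to the selection budget.  Accuracy,
sensitivity and specificity are reported per k and summarised as the
unweighted mean over k; the positive class is the more-impaired group
(higher group code).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .discrepancy import rank_features

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClassifierSpec:
    """Linear C-SVM configuration (kernel fixed; C default 1; optional
    z-score scaling with statistics taken from the training fold only)."""

    c: float = 1.0
    scaling: str = "none"  # "none" | "zscore"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("C must be positive")
        if self.scaling not in ("none", "zscore"):
            raise ValueError("scaling must be 'none' or 'zscore'")


@dataclasses.dataclass
class CvCurve:
    """LOOCV metrics as a function of feature count k = 1..K_max."""

    contrast: tuple[int, int]
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    k_max: int
    predictions: np.ndarray  # (K_max, n_subjects) predicted codes
    truths: np.ndarray

    @property
    def summary(self) -> dict:
        return {
            "contrast": list(self.contrast),
            "k_max": self.k_max,
            "mean_accuracy": float(self.accuracy.mean()),
            "mean_sensitivity": float(self.sensitivity.mean()),
            "mean_specificity": float(self.specificity.mean()),
        }

    def to_csv(self, path: str | Path, **meta) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "k": np.arange(1, self.k_max + 1),
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        ).to_csv(path, index=False)
        payload = {**self.summary, **meta}
        path.with_suffix(".json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def sens_spec(predictions, truths, positive_code: int) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP); positive class is
    the more-impaired group."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape:
        raise ValueError("predictions and truths must align")
    pos = true == positive_code
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present in truths")
    tp = int(np.sum(pos & (pred == positive_code)))
    fn = int(np.sum(pos & (pred != positive_code)))
    tn = int(np.sum(~pos & (pred != positive_code)))
    fp = int(np.sum(~pos & (pred == positive_code)))
    return tp / (tp + fn), tn / (tn + fp)


def _fit_predict(x_train, y_train, x_test, spec: ClassifierSpec, positive: int, negative: int) -> int:
    if spec.scaling == "zscore":
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd
    clf = SVC(kernel="linear", C=spec.c)
    clf.fit(x_train, y_train)
    df = float(clf.decision_function(x_test.reshape(1, -1))[0])
    if df == 0.0:
        logger.warning("SVM decision value exactly 0; resolving toward positive class")
        return positive
    # decision_function > 0 favours clf.classes_[1]
    return int(clf.classes_[1]) if df > 0 else int(clf.classes_[0])


def loocv_curve(
    features: np.ndarray,
    group_codes,
    spec: ClassifierSpec | None = None,
    k_max: int | None = None,
) -> CvCurve:
    """Leave-one-out curve with per-fold feature re-ranking.

    ``features`` is subjects x N for one two-group contrast.  ``k_max``
    defaults to the top-1% selection budget ceil(0.01 * N).
    """
    spec = spec or ClassifierSpec()
    features = np.asarray(features, dtype=float)
    codes = np.asarray(group_codes, dtype=int)
    n_sub, n_feat = features.shape
    groups = np.unique(codes)
    if groups.size != 2:
        raise ValueError("loocv_curve handles exactly two groups")
    if k_max is None:
        k_max = int(np.ceil(0.01 * n_feat))
    if k_max > n_feat:
        raise ValueError("k_max exceeds the number of features")
    negative, positive = int(groups[0]), int(groups[1])
    preds = np.empty((k_max, n_sub), dtype=int)
    for t in range(n_sub):
        train = np.ones(n_sub, dtype=bool)
        train[t] = False
        y_train = codes[train]
        if np.unique(y_train).size < 2:
            raise ValueError(f"fold {t}: training set contains a single class")
        table = rank_features(features[train], y_train, contrast=(negative, positive))
        for k in range(1, k_max + 1):
            cols = table.ranking[:k]
            preds[k - 1, t] = _fit_predict(
                features[train][:, cols], y_train, features[t, cols], spec, positive, negative
            )
    accuracy = (preds == codes[None, :]).mean(axis=1)
    sens = np.empty(k_max)
    specif = np.empty(k_max)
    for k in range(k_max):
        sens[k], specif[k] = sens_spec(preds[k], codes, positive)
    return CvCurve((negative, positive), accuracy, sens, specif, k_max, preds, codes.copy())


def average_accuracy(curve: CvCurve) -> float:
    """Unweighted mean of per-k accuracy over k = 1..K_max."""
    return float(curve.accuracy.mean())
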