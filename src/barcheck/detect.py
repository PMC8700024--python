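"""Violation decisions: transparent rules and a random-forest classifier.

The rule detector encodes the proportional-ink rules directly -- the
y-axis must start at zero, keep one scale, and not be partially hidden --
with the log-scale exemption.  It is exact when the features are exact.
Real parsing is noisy, so the probabilistic detector trains a random
forest on the feature table and exposes the decision threshold, which
trades precision against recall and predicted prevalence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import CONSISTENCY_TOL, FEATURE_COLUMNS, FeatureVector

__all__ = [
    "ViolationLabel",
    "Prediction",
    "ClassifierConfig",
    "ViolationClassifier",
    "rule_based_detect",
    "train_classifier",
    "predict",
    "threshold_sweep",
]

# "unspecified" is used for probabilistic predictions, which score a chart
# as a violation without attributing it to a single rule.
SUB_REASONS = ("nonzero_baseline", "inconsistent_scale", "hidden_axis", "none", "unspecified")


@dataclass(frozen=True)
class ViolationLabel:
    label: str          # "violation" | "other"
    sub_reason: str

    def __post_init__(self):
        if self.label not in ("violation", "other"):
            raise ValueError(f"label: unknown value {self.label!r}")
        if self.sub_reason not in SUB_REASONS:
            raise ValueError(f"sub_reason: unknown value {self.sub_reason!r}")
        if (self.label == "other") != (self.sub_reason == "none"):
            raise ValueError("label 'other' if and only if sub_reason 'none'")


@dataclass(frozen=True)
class Prediction:
    score: float
    threshold: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0 and 0.0 <= self.threshold <= 1.0):
            raise ValueError("score and threshold must lie in [0, 1]")

    @property
    def label(self) -> ViolationLabel:
        if self.score >= self.threshold:
            return ViolationLabel("violation", "unspecified")
        return ViolationLabel("other", "none")

    @property
    def is_violation(self) -> bool:
        return self.score >= self.threshold


def rule_based_detect(fv: FeatureVector, tol: float = CONSISTENCY_TOL) -> ViolationLabel:
    """Apply the proportional-ink rules to one feature vector.

    Precedence when several rules fire: hidden axis, then inconsistent
    scale, then non-zero baseline.  Log-scale axes are exempt.
    """
    if not fv.log_scale_flag:
        if fv.f3_lowest_inferred and fv.f1_lowest_tick_value > 0:
            return ViolationLabel("violation", "hidden_axis")
        if fv.f2_rate_consistency > tol:
            return ViolationLabel("violation", "inconsistent_scale")
        if fv.f1_lowest_tick_value > 0:
            return ViolationLabel("violation", "nonzero_baseline")
    return ViolationLabel("other", "none")


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest hyperparameters (standard defaults, recorded for
    reproducibility): 500 trees, sqrt feature subsampling, unlimited
    depth.  ``class_weight='balanced'`` is available for users who prefer
    recall over precision under the ~5% positive rate."""

    n_estimators: int = 500
    max_features: str = "sqrt"
    max_depth: Optional[int] = None
    class_weight: Optional[str] = None
    seed: int = 0


# Out-of-range sentinel for missing numeric features (a failed parse is
# information, not a dropped row).
MISSING_SENTINEL = -1.0


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(1 if lab == "violation" else 0)
        else:
            out.append(int(bool(lab)))
    return np.asarray(out, dtype=int)


class ViolationClassifier:
    """A fitted random forest plus its feature schema and provenance."""

    def __init__(self, config: ClassifierConfig = ClassifierConfig(),
                 feature_columns: Sequence[str] = tuple(FEATURE_COLUMNS)):
        self.config = config
        self.feature_columns = list(feature_columns)
        self.model = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            max_depth=config.max_depth,
            class_weight=config.class_weight,
            random_state=config.seed,
            n_jobs=1,
        )
        self.data_fingerprint: Optional[str] = None

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in table.columns]
        extra = [c for c in table.columns if c.startswith("f") and c not in self.feature_columns]
        if missing:
            raise ValueError(
                f"feature schema mismatch: missing {missing}, unexpected {extra or 'none'}"
            )
        X = table[self.feature_columns].to_numpy(dtype=float)
        return np.where(np.isnan(X), MISSING_SENTINEL, X)

    def fit(self, table: pd.DataFrame, labels: Sequence) -> "ViolationClassifier":
        y = _as_binary_labels(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("labels: need both classes present to train")
        X = self._matrix(table)
        # canonical row order: the fit (bootstrap draws included) depends
        # only on the data set, not on how the table happened to be sorted
        order = np.lexsort(tuple(X.T) + (y,))
        X, y = X[order], y[order]
        self.data_fingerprint = hashlib.sha256(
            X.tobytes() + y.tobytes() + ",".join(self.feature_columns).encode()
        ).hexdigest()
        self.model.fit(X, y)
        return self

    def predict_scores(self, table: pd.DataFrame) -> np.ndarray:
        X = self._matrix(table)
        proba = self.model.predict_proba(X)
        return proba[:, list(self.model.classes_).index(1)]

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(
            {
                "config": self.config,
                "feature_columns": self.feature_columns,
                "model": self.model,
                "data_fingerprint": self.data_fingerprint,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ViolationClassifier":
        blob = joblib.load(path)
        obj = cls(config=blob["config"], feature_columns=blob["feature_columns"])
        obj.model = blob["model"]
        obj.data_fingerprint = blob["data_fingerprint"]
        return obj


def train_classifier(
    table: pd.DataFrame,
    labels: Optional[Sequence] = None,
    config: ClassifierConfig = ClassifierConfig(),
    feature_columns: Sequence[str] = tuple(FEATURE_COLUMNS),
) -> ViolationClassifier:
    """Fit the violation classifier on a feature table.

    ``labels`` defaults to the table's ``label`` column.  Fitting is
    reproducible for a fixed config seed.
    """
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("labels: pass explicitly or include a 'label' column")
        labels = table["label"]
    clf = ViolationClassifier(config=config, feature_columns=feature_columns)
    return clf.fit(table, labels)


def _fv_to_frame(fv: Union[FeatureVector, pd.DataFrame, dict]) -> pd.DataFrame:
    if isinstance(fv, FeatureVector):
        return pd.DataFrame([fv.as_row()])
    if isinstance(fv, dict):
        return pd.DataFrame([fv])
    return fv


def predict(
    model: ViolationClassifier,
    fv: Union[FeatureVector, pd.DataFrame, dict],
    threshold: float = 0.5,
) -> Prediction:
    """Score one chart and threshold it into a label."""
    frame = _fv_to_frame(fv)
    score = float(model.predict_scores(frame)[0])
    return Prediction(score=score, threshold=threshold)


def threshold_sweep(
    model: ViolationClassifier,
    table: pd.DataFrame,
    labels: Sequence,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Precision, recall, F1 and predicted prevalence across thresholds.

    Lowering the threshold raises predicted prevalence; this is the
    mechanism for aligning a conservative classifier's prevalence with a
    human-annotated rate.
    """
    from .evaluate import confusion, f1_score, precision, recall

    grid = list(grid)
    if any(t < 0 or t > 1 for t in grid):
        raise ValueError("grid: thresholds must lie in [0, 1]")
    y = _as_binary_labels(labels)
    scores = model.predict_scores(table)
    rows = []
    for t in grid:
        pred = (scores >= t).astype(int)
        c = confusion(y, pred)
        rows.append(
            {
                "threshold": t,
                "precision": precision(c),
                "recall": recall(c),
                "f1": f1_score(c),
                "prevalence": float(pred.mean()),
            }
        )
    return pd.DataFrame(rows)
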