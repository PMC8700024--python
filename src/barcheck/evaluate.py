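"""Evaluation protocol: confusion counts, precision/recall, ROC AUC,
stratified k-fold cross-validation, and inter-annotator agreement.

The violation class is the positive class throughout.  Precision is
TP/(TP+FP); recall is TP/(TP+FN); both return ``None`` rather than a
silent zero when undefined.  AUC dispersion is conventionally reported as
a standard deviation and precision/recall dispersion as a standard error;
to avoid ambiguity every aggregate here carries both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .detect import ClassifierConfig, ViolationClassifier, _as_binary_labels

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "precision",
    "recall",
    "f1_score",
    "roc_auc",
    "stratified_cv",
    "cohens_kappa",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth: Sequence, pred: Sequence) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with violation as the positive class."""
    t = _as_binary_labels(truth)
    p = _as_binary_labels(pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: truth {len(t)} vs pred {len(p)}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def precision(c: ConfusionCounts) -> Optional[float]:
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def recall(c: ConfusionCounts) -> Optional[float]:
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def f1_score(c: ConfusionCounts) -> Optional[float]:
    p, r = precision(c), recall(c)
    if p is None or r is None or (p + r) == 0:
        return None
    return 2 * p * r / (p + r)


def roc_auc(scores: Sequence[float], truth: Sequence) -> float:
    """Rank-based AUC (ties get half credit), i.e. the probability that a
    random violation outscores a random non-violation."""
    y = _as_binary_labels(truth)
    if len(np.unique(y)) < 2:
        raise ValueError("truth: both classes must be present for AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    fold_metrics: list[dict]
    aggregates: dict
    k: int
    seed: int
    config: ClassifierConfig
    threshold: float

    def to_json(self) -> str:
        blob = asdict(self)
        blob["config"] = asdict(self.config)
        return json.dumps(blob, indent=2, sort_keys=True)


def _aggregate(values: list[Optional[float]]) -> dict:
    defined = np.array([v for v in values if v is not None], dtype=float)
    if defined.size == 0:
        return {"mean": None, "sd": None, "se": None, "n_defined": 0}
    return {
        "mean": float(defined.mean()),
        "sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
        "se": float(defined.std(ddof=1) / np.sqrt(defined.size)) if defined.size > 1 else 0.0,
        "n_defined": int(defined.size),
    }


def stratified_cv(
    table: pd.DataFrame,
    labels: Sequence,
    k: int = 5,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    threshold: float = 0.5,
    feature_columns: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Refit the forest on each of ``k`` stratified folds and score the
    held-out charts; every fold keeps the global class balance to within
    one chart."""
    y = _as_binary_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts.tolist()}")

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics = []
    kwargs = {}
    if feature_columns is not None:
        kwargs["feature_columns"] = feature_columns
    for fold_id, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        clf = ViolationClassifier(config=config, **kwargs)
        clf.fit(table.iloc[tr], y[tr])
        scores = clf.predict_scores(table.iloc[te])
        pred = (scores >= threshold).astype(int)
        c = confusion(y[te], pred)
        fold_metrics.append(
            {
                "fold": fold_id,
                "auc": roc_auc(scores, y[te]),
                "precision": precision(c),
                "recall": recall(c),
                "f1": f1_score(c),
                "n_test": int(len(te)),
                "n_test_pos": int(y[te].sum()),
            }
        )
    aggregates = {
        m: _aggregate([fm[m] for fm in fold_metrics]) for m in ("auc", "precision", "recall", "f1")
    }
    return EvalReport(
        fold_metrics=fold_metrics,
        aggregates=aggregates,
        k=k,
        seed=seed,
        config=config,
        threshold=threshold,
    )


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) between two
    binary annotators, with marginal-product expected agreement.

    Raises when expected agreement is 1 (both raters constant with
    identical marginals), where kappa is undefined.
    """
    ya = _as_binary_labels(a)
    yb = _as_binary_labels(b)
    if len(ya) != len(yb):
        raise ValueError("length mismatch between annotators")
    n = len(ya)
    if n == 0:
        raise ValueError("empty label lists")
    p_o = float(np.mean(ya == yb))
    pa1, pb1 = float(ya.mean()), float(yb.mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return (p_o - p_e) / (1 - p_e)
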