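"""Study-level statistics: prevalence with binomial error, exact 2x2
tests, and feature-distribution drift checks.

Prevalence is reported with the binomial standard error
``sqrt(p(1-p)/n)``; rendered percentages round to one decimal place.
The two-sided Fisher test uses the probability-mass convention: the
p-value sums hypergeometric point probabilities, over all tables with the
observed margins, that do not exceed the observed table's probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PrevalenceEstimate",
    "ContingencyTable2x2",
    "prevalence",
    "fisher_exact",
    "compare_feature_distributions",
]

BOOLEAN_FEATURES = ("f3", "f4", "log_flag")


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n: must be positive")
        if not (0 <= self.k <= self.n):
            raise ValueError("k: must satisfy 0 <= k <= n")

    @property
    def p(self) -> float:
        return self.k / self.n

    @property
    def se(self) -> float:
        return math.sqrt(self.p * (1 - self.p) / self.n)

    def render_percent(self) -> str:
        return f"{100 * self.p:.1f}% ± {100 * self.se:.1f}%"


def prevalence(k: int, n: int) -> PrevalenceEstimate:
    """Violation prevalence among processable charts with binomial SE."""
    return PrevalenceEstimate(k=int(k), n=int(n))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are groups, columns are (violation, no violation)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(table: Union[ContingencyTable2x2, Sequence[Sequence[int]]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    A degenerate margin (an empty row or column) makes the table
    uninformative; by convention p = 1 with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        warnings.warn("fisher_exact: degenerate margin, p-value 1 by convention")
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def compare_feature_distributions(
    fa: pd.DataFrame,
    fb: pd.DataFrame,
    continuous_threshold: float = 0.1,
    boolean_threshold: float = 0.1,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature divergence between two feature tables.

    Continuous features are compared with the two-sample Kolmogorov-
    Smirnov statistic, boolean ones with the absolute proportion
    difference; any feature exceeding its drift threshold is flagged.
    Used to check that an unlabeled scoring corpus looks like the labeled
    training corpus before trusting predictions on it.
    """
    if columns is None:
        columns = [c for c in fa.columns if c.startswith("f") or c == "log_flag"]
    missing = [c for c in columns if c not in fb.columns]
    if missing or any(c not in fa.columns for c in columns):
        raise ValueError(f"feature schema mismatch: {missing or columns}")
    rows = []
    for c in columns:
        xa = fa[c].to_numpy(dtype=float)
        xb = fb[c].to_numpy(dtype=float)
        if c in BOOLEAN_FEATURES:
            stat = abs(float(np.mean(xa)) - float(np.mean(xb)))
            kind, thr = "prop_diff", boolean_threshold
        else:
            stat = float(sps.ks_2samp(xa, xb).statistic)
            kind, thr = "ks", continuous_threshold
        rows.append({"feature": c, "kind": kind, "statistic": stat, "flagged": stat > thr})
    return pd.DataFrame(rows)
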