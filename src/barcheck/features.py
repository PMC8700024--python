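"""The seven-feature representation of a parsed bar chart.

The features encode the proportional-ink rules -- the lowest y-axis label
should be zero, and the step between neighbouring labels should be
constant -- together with parsing-quality signals (text probability, OCR
confidence, chart-class probability) that let a probabilistic classifier
discount charts whose reconstruction is unreliable:

f1  value of the lowest y-axis label (read, or extrapolated when the
    lowest label sits far above the x-axis)
f2  inconsistency of the label-to-label increase: max relative deviation
    of adjacent tick differences from their median (0 = one scale)
f3  whether f1 had to be inferred rather than read
f4  whether the y-axis mixes integer- and decimal-formatted labels
f5  mean text probability of the y-axis boxes
f6  mean OCR confidence of the y-axis boxes
f7  probability that the figure is a bar chart

An auxiliary ``log_flag`` marks axes whose labels grow by a constant
*ratio*: log scales also break ink proportionality but are an accepted
convention, so they are exempted from the violation rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import median
from typing import TYPE_CHECKING, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .vision import AxisModel, TextBox

__all__ = [
    "LabelParseError",
    "FeatureVector",
    "TickRates",
    "parse_numeric_label",
    "try_parse_numeric_label",
    "parse_tick_labels",
    "tick_increase_rates",
    "infer_lowest_tick",
    "extract_features",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "CONSISTENCY_TOL",
]

FEATURE_COLUMNS = ["f1", "f2", "f3", "f4", "f5", "f6", "f7"]
TABLE_COLUMNS = ["chart_id"] + FEATURE_COLUMNS + ["log_flag", "label"]

#: Relative tolerance separating "one scale" from a broken scale while
#: absorbing label rounding; also the constancy tolerance on adjacent
#: ratios for the log-scale flag.
CONSISTENCY_TOL = 0.02

#: A tick label counts as "far from the x-axis" when its gap to the
#: baseline exceeds this multiple of the median inter-tick spacing:
#: below a full spacing (to catch a single hidden tick) but above half
#: (to tolerate label-centering offset).
EXTRAPOLATION_FACTOR = 0.6

#: Cap on f2 so that wildly corrupted parses stay on a bounded scale.
F2_CAP = 50.0


class LabelParseError(ValueError):
    """A tick label does not match the numeric-label grammar."""


# Optional sign; digits either plainly or with well-formed comma grouping;
# optional decimal part; optional exponent; optional trailing percent.
_NUMBER_RE = re.compile(
    r"""^\s*
        (?P<sign>[+-])?
        (?P<int>\d{1,3}(?:,\d{3})+|\d+)?
        (?P<frac>\.\d+)?
        (?P<exp>[eE][+-]?\d+)?
        (?P<pct>%)?
        \s*$""",
    re.VERBOSE,
)


def parse_numeric_label(text: str) -> float:
    """Parse one tick label. Raises :class:`LabelParseError` otherwise.

    The trailing ``%`` is accepted but *not* applied here; percent
    normalization is an axis-level decision (see :func:`parse_tick_labels`).
    """
    value, _ = _parse(text)
    if value is None:
        raise LabelParseError(f"not a numeric tick label: {text!r}")
    return value


def try_parse_numeric_label(text: str) -> tuple[Optional[float], bool]:
    """(value or None, had_percent_suffix) without raising."""
    return _parse(text)


def _parse(text: str) -> tuple[Optional[float], bool]:
    if not text:
        return None, False
    m = _NUMBER_RE.match(text)
    if not m:
        return None, False
    if m.group("int") is None and m.group("frac") is None:
        return None, False
    body = (m.group("sign") or "") + (m.group("int") or "").replace(",", "") + (
        m.group("frac") or ""
    ) + (m.group("exp") or "")
    try:
        return float(body), m.group("pct") is not None
    except ValueError:  # pragma: no cover - grammar should prevent this
        return None, False


def parse_tick_labels(texts: Sequence[str]) -> list[Optional[float]]:
    """Parse an axis worth of labels; ``None`` marks parse failures.

    Values are divided by 100 only when *every* label on the axis carries
    a percent sign -- a lone ``%`` is treated as noise.
    """
    parsed = [_parse(t) for t in texts]
    values = [v for v, _ in parsed]
    if values and all(v is not None for v in values) and all(p for _, p in parsed):
        values = [v / 100.0 for v in values]
    return values


@dataclass
class TickRates:
    differences: list[float]
    deviation: float          # f2
    log_flag: bool
    low_info: bool = False


def tick_increase_rates(values: Sequence[float]) -> TickRates:
    """Consistency of the y-axis scale from ordered tick values.

    With fewer than 3 values the axis carries too little information to
    judge the scale: f2 is 0 by convention and the result is flagged.
    """
    values = list(values)
    if len(values) < 3:
        return TickRates(differences=_diffs(values), deviation=0.0, log_flag=False, low_info=True)

    diffs = _diffs(values)
    med = median(diffs)
    denom = abs(med) if med != 0 else 1e-9
    deviation = min(max(abs(d - med) / denom for d in diffs), F2_CAP)

    log_flag = False
    if all(v > 0 for v in values) and deviation > CONSISTENCY_TOL:
        ratios = [b / a for a, b in zip(values, values[1:])]
        med_r = median(ratios)
        if med_r > 0 and max(abs(r - med_r) / med_r for r in ratios) <= CONSISTENCY_TOL:
            log_flag = True
    return TickRates(differences=diffs, deviation=deviation, log_flag=log_flag)


def _diffs(values: Sequence[float]) -> list[float]:
    return [b - a for a, b in zip(values, values[1:])]


def infer_lowest_tick(axis: "AxisModel") -> tuple[float, bool]:
    """(f1, f3): the lowest y-axis value, extrapolated when necessary.

    When the gap between the lowest parsed tick and the x-axis baseline
    exceeds ``EXTRAPOLATION_FACTOR`` times the median inter-tick pixel
    spacing, the arithmetic tick sequence is continued downward to the row
    nearest the baseline and that value is returned with f3 = True.  An
    undetected baseline conservatively yields (lowest parsed value, True).
    """
    parsed = axis.parsed_ticks()  # (row, value), value-ascending
    if len(parsed) < 2:
        raise ValueError("infer_lowest_tick: need at least 2 parsed ticks")
    lowest_row, lowest_value = parsed[0]
    if axis.baseline_row is None:
        return lowest_value, True
    row_gaps = [abs(parsed[i][0] - parsed[i + 1][0]) for i in range(len(parsed) - 1)]
    spacing = median(row_gaps)
    gap = axis.baseline_row - lowest_row
    if spacing <= 0 or gap <= EXTRAPOLATION_FACTOR * spacing:
        return lowest_value, False
    step = median(_diffs([v for _, v in parsed]))
    n_missing = int(round(gap / spacing))
    return lowest_value - n_missing * step, True


@dataclass
class FeatureVector:
    f1_lowest_tick_value: float
    f2_rate_consistency: float
    f3_lowest_inferred: bool
    f4_mixed_int_float: bool
    f5_text_probability: float
    f6_ocr_confidence: float
    f7_barchart_probability: float
    log_scale_flag: bool = False
    low_info: bool = False

    def as_row(self) -> dict:
        return {
            "f1": self.f1_lowest_tick_value,
            "f2": self.f2_rate_consistency,
            "f3": float(self.f3_lowest_inferred),
            "f4": float(self.f4_mixed_int_float),
            "f5": self.f5_text_probability,
            "f6": self.f6_ocr_confidence,
            "f7": self.f7_barchart_probability,
            "log_flag": float(self.log_scale_flag),
        }


def _is_decimal_formatted(text: str) -> bool:
    return "." in text


def extract_features(
    axis: "AxisModel",
    boxes: Sequence["TextBox"],
    chart_prob: float = 1.0,
) -> FeatureVector:
    """Assemble the feature vector for one parsed chart.

    Raises :class:`~barcheck.vision.UnprocessableChartError` when fewer
    than two tick labels parsed -- such charts cannot yield f1 and are
    excluded from prevalence denominators, as a real pipeline excludes
    charts whose axis it cannot reconstruct.
    """
    from .vision import UnprocessableChartError

    y_boxes = [b for b in boxes if b.role == "y_tick"]
    if not y_boxes:
        raise UnprocessableChartError("no y-axis tick boxes")
    parsed = axis.parsed_ticks()
    if len(parsed) < 2:
        raise UnprocessableChartError("fewer than 2 parseable y-axis tick labels")

    # Axis order (descending pixel row) is the order the reader sees; a
    # corrupted label that breaks monotonicity shows up as a large f2.
    by_row = sorted(((r, v) for r, v, _ in axis.ticks if v is not None), key=lambda t: -t[0])
    rates = tick_increase_rates([v for _, v in by_row])

    f1, f3 = infer_lowest_tick(axis)

    parsed_texts = [b.text for _, v, b in axis.ticks if v is not None and b is not None]
    stripped = [t.strip().rstrip("%") for t in parsed_texts]
    f4 = any(_is_decimal_formatted(t) for t in stripped) and any(
        not _is_decimal_formatted(t) for t in stripped
    )

    f5 = sum(b.text_probability for b in y_boxes) / len(y_boxes)
    f6 = sum(b.ocr_confidence for b in y_boxes) / len(y_boxes)

    return FeatureVector(
        f1_lowest_tick_value=f1,
        f2_rate_consistency=rates.deviation,
        f3_lowest_inferred=f3,
        f4_mixed_int_float=bool(f4),
        f5_text_probability=float(f5),
        f6_ocr_confidence=float(f6),
        f7_barchart_probability=float(chart_prob),
        log_scale_flag=rates.log_flag,
        low_info=rates.low_info,
    )
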