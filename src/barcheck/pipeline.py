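"""End-to-end convenience paths: chart -> parse -> features -> table.

Two routes exist.  The *oracle* route consumes generator ground truth
with controllable character-confusion and tick-row jitter, isolating the
feature and classifier stages from pixel parsing.  The *pixel* route runs
the full classical-CV parser on a raster.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import chartgen, features, vision

__all__ = [
    "chart_probability_stub",
    "oracle_feature_row",
    "corpus_feature_table",
    "parse_image",
]


def chart_probability_stub(rng: np.random.Generator) -> float:
    """Stand-in for a chart-type classifier's bar-chart probability.

    The synthetic corpus contains only bar charts, so the stub returns a
    high probability with small jitter, uninformative about violations.
    """
    return float(np.clip(1.0 - abs(rng.normal(0.0, 0.03)), 0.0, 1.0))


def oracle_feature_row(
    gt: "chartgen.GroundTruth",
    confusion_rate: float = 0.0,
    row_jitter_px: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> features.FeatureVector:
    """Ground truth -> feature vector through the oracle parser."""
    rng = rng if rng is not None else np.random.default_rng(0)
    axis, boxes = vision.oracle_parse(
        gt, confusion_rate=confusion_rate, row_jitter_px=row_jitter_px, rng=rng
    )
    return features.extract_features(axis, boxes, chart_prob=chart_probability_stub(rng))


def corpus_feature_table(
    n: int,
    violation_rate: float = 0.055,
    mix: Optional[dict] = None,
    seed: int = 0,
    confusion_rate: float = 0.0,
    row_jitter_px: int = 0,
    log_fraction: float = 0.12,
) -> pd.DataFrame:
    """Sample a synthetic corpus and featurize it through the oracle route.

    Returns a table with columns ``chart_id, f1..f7, log_flag, label,
    sub_reason``; charts whose axis could not be reconstructed (fewer than
    two parseable tick labels) are excluded, and their count is recorded
    in ``df.attrs['n_unprocessable']``.
    """
    specs = chartgen.sample_corpus(
        n, violation_rate, mix=mix, seed=seed, log_fraction=log_fraction
    )
    noise_rng = np.random.default_rng((seed + 1) % 2**31)
    rows = []
    n_unprocessable = 0
    for i, spec in enumerate(specs):
        gt = chartgen.plan_chart(spec)
        try:
            fv = oracle_feature_row(
                gt, confusion_rate=confusion_rate, row_jitter_px=row_jitter_px, rng=noise_rng
            )
        except vision.UnprocessableChartError:
            n_unprocessable += 1
            continue
        row = {"chart_id": f"chart-{i:05d}", **fv.as_row()}
        row["label"] = gt.violation_label.label
        row["sub_reason"] = gt.violation_label.sub_reason
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_unprocessable"] = n_unprocessable
    df.attrs["n_requested"] = n
    return df


def parse_image(
    image: Image.Image,
    backend: str = "oracle",
    ground_truth: Optional["chartgen.GroundTruth"] = None,
    chart_prob: float = 1.0,
    confusion_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> features.FeatureVector:
    """Full pixel pipeline: localize, recognize, assign roles, reconstruct
    the axis, and extract features for one single-panel chart."""
    boxes = vision.localize_text(image)
    boxes = vision.recognize_text(
        image, boxes, backend=backend, ground_truth=ground_truth,
        confusion_rate=confusion_rate, rng=rng,
    )
    boxes = vision.classify_text_roles(boxes, image.size)
    axis = vision.detect_axes(image, boxes)
    return features.extract_features(axis, boxes, chart_prob=chart_prob)
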