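"""Deterministic synthetic bar charts with pixel-exact ground truth.

Every chart is fully described by a :class:`ChartSpec`; rendering the same
spec twice yields a bit-identical raster.  The generator produces the three
kinds of proportional-ink violations -- a y-axis that does not start at
zero, a broken (multi-scale) y-axis, and a partially hidden y-axis -- plus
rule-conforming charts on linear or logarithmic scales.  Log-scale charts
are deliberately labelled as non-violations: log axes are an accepted
convention even though bar area is not proportional to value on them.

Coordinate convention (used throughout the package): raster origin is the
top-left corner, rows grow downward, and all boxes are half-open integer
pixel rectangles ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .detect import ViolationLabel

__all__ = [
    "ChartStyle",
    "ChartSpec",
    "GTBox",
    "GroundTruth",
    "ManifestRecord",
    "CorpusManifest",
    "generate_chart",
    "plan_chart",
    "sample_spec",
    "sample_corpus",
    "generate_corpus",
    "compose_compound",
    "expected_label",
    "validate_spec",
]

VIOLATION_KINDS = ("none", "nonzero_baseline", "inconsistent_scale", "hidden_axis")
SCALE_KINDS = ("linear", "log", "broken")

# Canvas geometry: small canvases emulate the low-resolution figures found
# in open-access figure dumps and stress the parser realistically.
CANVAS_W, CANVAS_H = 640, 480
MARGIN_LEFT, MARGIN_RIGHT, MARGIN_TOP, MARGIN_BOTTOM = 90, 20, 60, 60
AXIS_X = MARGIN_LEFT                 # column of the y-axis line
PLOT_RIGHT = CANVAS_W - MARGIN_RIGHT
PLOT_TOP = MARGIN_TOP                # row of the topmost tick
BASELINE_ROW = CANVAS_H - MARGIN_BOTTOM

GRID_COLOR = (225, 225, 225)
INK = (0, 0, 0)
BACKGROUND = (255, 255, 255)

# Chromatic bar fills, deliberately distinct from the achromatic text/axis
# ink so the classical text localizer can separate them.
PALETTE = [
    (70, 130, 180),   # steel blue
    (205, 92, 92),    # indian red
    (60, 179, 113),   # medium sea green
    (218, 165, 32),   # goldenrod
    (147, 112, 219),  # medium purple
    (100, 149, 237),  # cornflower
]

_Y_TITLES = ("Count", "Signal", "Yield", "Rate", "Score", "Level", "Mean value")
_X_TITLES = ("Group", "Sample", "Condition", "Batch", "Site", "Treatment")
_TITLE_WORDS = ("Observed", "Relative", "Total", "Adjusted", "Estimated", "Baseline")
_CATEGORIES = "ABCDEFGHJK"


def _font(size: int) -> ImageFont.FreeTypeFont:
    if size not in _FONT_CACHE:
        _FONT_CACHE[size] = ImageFont.truetype(_FONT_PATH, size)
    return _FONT_CACHE[size]


def _find_font_path() -> str:
    from matplotlib import font_manager

    return font_manager.findfont("DejaVu Sans")


_FONT_PATH = _find_font_path()
_FONT_CACHE: dict[int, ImageFont.FreeTypeFont] = {}
# One throwaway draw context for text measurement; avoids rendering just to
# compute ground-truth boxes.
_MEASURER = ImageDraw.Draw(Image.new("RGB", (1, 1)))


@dataclass(frozen=True)
class ChartStyle:
    """Visual styling knobs; randomized per chart to exercise the numeric
    label grammar (decimals, thousands separators) and the localizer."""

    font_size: int = 12
    bar_color: tuple[int, int, int] = PALETTE[0]
    grid: bool = False
    decimals: int = 0
    thousands: bool = False
    percent: bool = False
    trim_zeros: bool = False
    with_title: bool = True


@dataclass(frozen=True)
class ChartSpec:
    """Complete recipe for one synthetic chart.

    ``tick_step`` is the additive step between ticks on linear scales and
    the multiplicative factor on log scales.  ``break_segment`` is
    ``(restart_value, post_step)`` for broken axes, with
    ``break_pre_ticks`` ticks drawn before the break.  ``hidden_fraction``
    is the fraction of the plot height cropped from the bottom for
    partially hidden axes.
    """

    n_bars: int
    bar_values: tuple[float, ...]
    baseline_value: float
    tick_step: float
    n_ticks: int
    scale_kind: str
    violation_kind: str
    break_segment: Optional[tuple[float, float]] = None
    break_pre_ticks: int = 0
    hidden_fraction: float = 0.0
    style: ChartStyle = field(default_factory=ChartStyle)
    seed: int = 0


@dataclass(frozen=True)
class GTBox:
    x0: int
    y0: int
    x1: int
    y1: int
    text: str
    role: str

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass
class GroundTruth:
    """Exhaustive annotation of one rendered chart."""

    text_boxes: list[GTBox]
    tick_values: list[tuple[int, float]]     # (pixel row, numeric value), value-ascending
    baseline_row: Optional[int]              # None when the x-axis is cropped away
    violation_label: ViolationLabel
    sub_bounds: Optional[list[tuple[int, int, int, int]]] = None
    image_size: tuple[int, int] = (CANVAS_W, CANVAS_H)


def expected_label(spec: ChartSpec) -> ViolationLabel:
    if spec.violation_kind == "none":
        return ViolationLabel("other", "none")
    return ViolationLabel("violation", spec.violation_kind)


def validate_spec(spec: ChartSpec) -> None:
    """Reject inconsistent specs with a diagnostic naming the field."""
    if spec.scale_kind not in SCALE_KINDS:
        raise ValueError(f"scale_kind: unknown value {spec.scale_kind!r}")
    if spec.violation_kind not in VIOLATION_KINDS:
        raise ValueError(f"violation_kind: unknown value {spec.violation_kind!r}")
    if spec.n_bars < 1 or spec.n_bars != len(spec.bar_values):
        raise ValueError("n_bars: must be >= 1 and match len(bar_values)")
    if spec.n_ticks < 3:
        raise ValueError("n_ticks: need at least 3 ticks")
    if spec.tick_step <= 0:
        raise ValueError("tick_step: must be positive")
    if spec.scale_kind == "log":
        if spec.tick_step <= 1:
            raise ValueError("tick_step: log factor must exceed 1")
        if spec.baseline_value <= 0:
            raise ValueError("baseline_value: log axis must start above 0")
        if spec.violation_kind != "none":
            raise ValueError("violation_kind: log-scale charts are non-violations")
    if (spec.violation_kind == "nonzero_baseline") != (
        spec.baseline_value > 0 and spec.scale_kind == "linear"
    ):
        raise ValueError(
            "violation_kind: nonzero_baseline requires (and is implied by) "
            "baseline_value > 0 on a linear scale"
        )
    if (spec.violation_kind == "inconsistent_scale") != (spec.scale_kind == "broken"):
        raise ValueError("violation_kind: inconsistent_scale <=> scale_kind broken")
    if spec.scale_kind == "broken":
        if spec.break_segment is None or spec.break_pre_ticks < 2:
            raise ValueError("break_segment: broken axis needs a break and >= 2 pre-break ticks")
        restart, post_step = spec.break_segment
        if post_step <= 0:
            raise ValueError("break_segment: post-break step must be positive")
        if restart <= (spec.break_pre_ticks - 1) * spec.tick_step:
            raise ValueError("break_segment: restart value must exceed the last pre-break tick")
        if spec.break_pre_ticks >= spec.n_ticks:
            raise ValueError("break_pre_ticks: must leave ticks after the break")
    if spec.violation_kind == "hidden_axis":
        if not (0 < spec.hidden_fraction < 1):
            raise ValueError("hidden_fraction: must be in (0, 1) for hidden_axis charts")
        if spec.scale_kind != "linear" or spec.baseline_value != 0:
            raise ValueError("violation_kind: hidden_axis charts are linear with a zero baseline")
    elif spec.hidden_fraction != 0:
        raise ValueError("hidden_fraction: only hidden_axis charts may crop the axis")
    ticks = tick_display_values(spec)
    vmax = ticks[-1]
    lo = spec.baseline_value
    for v in spec.bar_values:
        if not (lo <= v <= vmax):
            raise ValueError(f"bar_values: {v} outside the axis range [{lo}, {vmax}]")


def tick_display_values(spec: ChartSpec) -> list[float]:
    """Tick values as printed on the axis (before any percent normalization)."""
    if spec.scale_kind == "linear":
        return [spec.baseline_value + i * spec.tick_step for i in range(spec.n_ticks)]
    if spec.scale_kind == "log":
        return [spec.baseline_value * spec.tick_step**i for i in range(spec.n_ticks)]
    restart, post_step = spec.break_segment
    pre = [i * spec.tick_step for i in range(spec.break_pre_ticks)]
    post = [restart + j * post_step for j in range(spec.n_ticks - spec.break_pre_ticks)]
    return pre + post


def _format_tick(value: float, style: ChartStyle) -> str:
    if style.percent:
        return f"{value:.0f}%"
    if style.thousands:
        s = f"{value:,.{style.decimals}f}"
    else:
        s = f"{value:.{style.decimals}f}"
    if style.trim_zeros and "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def _tick_rows(spec: ChartSpec) -> list[int]:
    """Pixel rows of the ticks, value-ascending.  All three scale kinds
    place ticks at (near) uniform pixel spacing -- that uniformity is what
    makes a broken axis deceptive."""
    span = BASELINE_ROW - PLOT_TOP
    k = spec.n_ticks - 1
    return [BASELINE_ROW - round(i * span / k) for i in range(spec.n_ticks)]


def _value_to_row(spec: ChartSpec, ticks: list[float], rows: list[int], v: float) -> int:
    if spec.scale_kind == "linear":
        frac = (v - ticks[0]) / (ticks[-1] - ticks[0])
    elif spec.scale_kind == "log":
        frac = (np.log(v) - np.log(ticks[0])) / (np.log(ticks[-1]) - np.log(ticks[0]))
    else:
        # Piecewise through the tick anchors: exactly the distorted mapping
        # a broken axis imposes on the reader.
        return int(round(float(np.interp(v, ticks, rows))))
    return BASELINE_ROW - round(frac * (BASELINE_ROW - PLOT_TOP))


@dataclass
class _TextElem:
    text: str
    role: str
    xy: tuple[int, int]
    anchor: str
    rotated: bool = False
    tick_row: Optional[int] = None


def _measure(elem: _TextElem, font: ImageFont.FreeTypeFont) -> tuple[int, int, int, int]:
    if not elem.rotated:
        x0, y0, x1, y1 = _MEASURER.textbbox(elem.xy, elem.text, font=font, anchor=elem.anchor)
        return int(x0), int(y0), int(x1), int(y1) + 1
    # Rotated text is measured horizontally, then the box transposed around
    # the requested center point.
    l, t, r, b = _MEASURER.textbbox((0, 0), elem.text, font=font, anchor="la")
    w, h = r - l, b - t + 1
    cx, cy = elem.xy
    return (cx - h // 2, cy - w // 2, cx - h // 2 + h, cy - w // 2 + w)


def _layout(spec: ChartSpec):
    """Shared geometry for both ground truth and rendering."""
    validate_spec(spec)
    style = spec.style
    font = _font(style.font_size)
    local = np.random.default_rng(spec.seed % 2**31)

    ticks = tick_display_values(spec)
    rows = _tick_rows(spec)

    elems: list[_TextElem] = []
    for v, r in zip(ticks, rows):
        elems.append(
            _TextElem(_format_tick(v, style), "y_tick", (AXIS_X - 8, r), "rm", tick_row=r)
        )

    slot = (PLOT_RIGHT - AXIS_X) / spec.n_bars
    bar_w = max(4, int(slot * 0.7))
    bars = []
    for i, v in enumerate(spec.bar_values):
        cx = AXIS_X + (i + 0.5) * slot
        top = _value_to_row(spec, ticks, rows, v)
        bars.append((int(cx - bar_w / 2), top, int(cx + bar_w / 2), BASELINE_ROW))
        elems.append(
            _TextElem(_CATEGORIES[i % len(_CATEGORIES)], "x_tick", (int(cx), BASELINE_ROW + 8), "ma")
        )

    y_title = _Y_TITLES[spec.seed % len(_Y_TITLES)]
    x_title = _X_TITLES[(spec.seed // 7) % len(_X_TITLES)]
    elems.append(_TextElem(y_title, "y_title", (18, (PLOT_TOP + BASELINE_ROW) // 2), "mm", rotated=True))
    elems.append(_TextElem(x_title, "x_title", ((AXIS_X + PLOT_RIGHT) // 2, CANVAS_H - 22), "mm"))
    if style.with_title:
        w1 = _TITLE_WORDS[spec.seed % len(_TITLE_WORDS)]
        elems.append(_TextElem(f"{w1} {y_title.lower()}", "title", ((AXIS_X + PLOT_RIGHT) // 2, 24), "mm"))

    cutoff = None
    if spec.violation_kind == "hidden_axis":
        cutoff = BASELINE_ROW - round(spec.hidden_fraction * (BASELINE_ROW - PLOT_TOP))

    del local  # reserved for future style jitter; spec fields stay authoritative
    return ticks, rows, elems, bars, font, cutoff


def plan_chart(spec: ChartSpec) -> GroundTruth:
    """Ground truth of ``generate_chart(spec)`` without rasterizing.

    The oracle parsing backend consumes only this geometry, so large
    corpora for classifier experiments do not need pixel rendering.
    """
    ticks, rows, elems, _bars, font, cutoff = _layout(spec)
    style = spec.style
    height = CANVAS_H if cutoff is None else cutoff

    boxes: list[GTBox] = []
    kept_tick_rows: set[int] = set()
    for e in elems:
        x0, y0, x1, y1 = _measure(e, font)
        if cutoff is not None and y1 > cutoff:
            continue  # fully or partially cropped elements are not annotated
        boxes.append(GTBox(x0, y0, x1, y1, e.text, e.role))
        if e.role == "y_tick":
            kept_tick_rows.add(e.tick_row)

    tick_values = []
    for v, r in zip(ticks, rows):
        if r not in kept_tick_rows:
            continue
        gt_value = _parsed_value(v, style)
        tick_values.append((r, gt_value))
    tick_values.sort(key=lambda t: t[1])

    baseline = BASELINE_ROW if cutoff is None else None
    return GroundTruth(
        text_boxes=boxes,
        tick_values=tick_values,
        baseline_row=baseline,
        violation_label=expected_label(spec),
        image_size=(CANVAS_W, height),
    )


def _parsed_value(v: float, style: ChartStyle) -> float:
    """The numeric value a correct reading of the printed label yields."""
    s = _format_tick(v, style)
    if s.endswith("%"):
        return float(s[:-1]) / 100.0
    return float(s.replace(",", ""))


def generate_chart(spec: ChartSpec) -> tuple[Image.Image, GroundTruth]:
    """Render one chart.  Identical specs give bit-identical rasters."""
    ticks, rows, elems, bars, font, cutoff = _layout(spec)
    style = spec.style

    img = Image.new("RGB", (CANVAS_W, CANVAS_H), BACKGROUND)
    draw = ImageDraw.Draw(img)

    if style.grid:
        for r in rows[1:]:
            draw.line([(AXIS_X + 1, r), (PLOT_RIGHT, r)], fill=GRID_COLOR, width=1)

    for x0, top, x1, bottom in bars:
        draw.rectangle([x0, top, x1, bottom - 1], fill=style.bar_color)

    # Axis lines and tick marks.
    draw.line([(AXIS_X, PLOT_TOP - 4), (AXIS_X, BASELINE_ROW)], fill=INK, width=1)
    draw.line([(AXIS_X, BASELINE_ROW), (PLOT_RIGHT, BASELINE_ROW)], fill=INK, width=1)
    for r in rows:
        draw.line([(AXIS_X - 5, r), (AXIS_X, r)], fill=INK, width=1)

    if spec.scale_kind == "broken":
        # Conventional double-slash break glyph between the two segments.
        r_lo = rows[spec.break_pre_ticks - 1]
        r_hi = rows[spec.break_pre_ticks]
        rb = (r_lo + r_hi) // 2
        draw.rectangle([AXIS_X - 1, rb - 5, AXIS_X + 1, rb + 5], fill=BACKGROUND)
        for dy in (-3, 3):
            draw.line([(AXIS_X - 4, rb + dy + 3), (AXIS_X + 4, rb + dy - 3)], fill=INK, width=1)

    for e in elems:
        if not e.rotated:
            draw.text(e.xy, e.text, fill=INK, font=font, anchor=e.anchor)
        else:
            l, t, r, b = _MEASURER.textbbox((0, 0), e.text, font=font, anchor="la")
            tmp = Image.new("RGB", (r - l + 2, b - t + 2), BACKGROUND)
            ImageDraw.Draw(tmp).text((-l + 1, -t + 1), e.text, fill=INK, font=font)
            tmp = tmp.rotate(90, expand=True)
            x0, y0, x1, y1 = _measure(e, font)
            img.paste(tmp, (x0, y0))

    if cutoff is not None:
        img = img.crop((0, 0, CANVAS_W, cutoff))

    return img, plan_chart(spec)


# ---------------------------------------------------------------------------
# Spec sampling

DEFAULT_VIOLATION_MIX = {
    "nonzero_baseline": 0.5,
    "inconsistent_scale": 0.25,
    "hidden_axis": 0.25,
}

_INT_STEPS = (1, 2, 5, 10, 20, 25, 50, 100, 200, 500, 1000, 2000)
_DEC1_STEPS = (0.5, 2.5)
_DEC2_STEPS = (0.25, 0.05)


def _sample_style(rng: np.random.Generator, *, percent_ok: bool) -> tuple[ChartStyle, float]:
    """Returns a style plus the tick step that matches its decimal places."""
    decimals = int(rng.choice([0, 0, 0, 1, 2]))
    percent = bool(percent_ok and decimals == 0 and rng.random() < 0.10)
    if percent:
        step = float(rng.choice([10, 20, 25]))
    elif decimals == 0:
        step = float(rng.choice(_INT_STEPS))
    elif decimals == 1:
        step = float(rng.choice(_DEC1_STEPS))
    else:
        step = float(rng.choice(_DEC2_STEPS))
    style = ChartStyle(
        font_size=int(rng.integers(8, 17)),
        bar_color=PALETTE[int(rng.integers(len(PALETTE)))],
        grid=bool(rng.random() < 0.4),
        decimals=decimals,
        thousands=bool(step >= 1000 and rng.random() < 0.7),
        percent=percent,
        trim_zeros=bool(decimals > 0 and rng.random() < 0.5),
        with_title=bool(rng.random() < 0.8),
    )
    return style, step


def _sample_bars(rng: np.random.Generator, n: int, lo: float, hi: float) -> tuple[float, ...]:
    vals = rng.uniform(lo + 0.05 * (hi - lo), lo + 0.97 * (hi - lo), size=n)
    return tuple(round(float(v), 4) for v in vals)


def sample_spec(
    rng: np.random.Generator,
    violation_kind: str = "none",
    log_fraction: float = 0.12,
) -> ChartSpec:
    """Draw one realistic ChartSpec of the requested violation kind.

    ``log_fraction`` is the share of log-scale axes among rule-conforming
    charts (log charts are always non-violations).
    """
    seed = int(rng.integers(2**31))
    n_bars = int(rng.integers(3, 9))

    if violation_kind == "none" and rng.random() < log_fraction:
        factor = float(rng.choice([2.0, 10.0]))
        n_ticks = int(rng.integers(4, 7)) if factor == 2.0 else int(rng.integers(4, 6))
        style = ChartStyle(
            font_size=int(rng.integers(8, 17)),
            bar_color=PALETTE[int(rng.integers(len(PALETTE)))],
            grid=bool(rng.random() < 0.4),
            decimals=0,
            thousands=bool(factor == 10.0 and n_ticks >= 4 and rng.random() < 0.5),
            with_title=bool(rng.random() < 0.8),
        )
        v0 = 1.0
        vmax = v0 * factor ** (n_ticks - 1)
        bars = tuple(
            round(float(np.exp(rng.uniform(np.log(v0 * 1.05), np.log(vmax * 0.97)))), 4)
            for _ in range(n_bars)
        )
        return ChartSpec(
            n_bars=n_bars, bar_values=bars, baseline_value=v0, tick_step=factor,
            n_ticks=n_ticks, scale_kind="log", violation_kind="none",
            style=style, seed=seed,
        )

    if violation_kind == "hidden_axis":
        style, step = _sample_style(rng, percent_ok=False)
        m = int(rng.integers(1, 3))         # fully hidden tick count
        n_ticks = int(rng.integers(m + 4, 8))
        rows = [
            BASELINE_ROW - round(i * (BASELINE_ROW - PLOT_TOP) / (n_ticks - 1))
            for i in range(n_ticks)
        ]
        # Crop two rows below tick m's center: ticks 0..m-1 (and the x-axis)
        # vanish and tick m's label is sliced through, mimicking the partially
        # hidden axes seen in published figures.
        cutoff = rows[m] + 2
        frac = (BASELINE_ROW - cutoff) / (BASELINE_ROW - PLOT_TOP)
        vmax = (n_ticks - 1) * step
        return ChartSpec(
            n_bars=n_bars,
            bar_values=_sample_bars(rng, n_bars, (m + 1) * step, vmax),
            baseline_value=0.0, tick_step=step, n_ticks=n_ticks,
            scale_kind="linear", violation_kind="hidden_axis",
            hidden_fraction=frac, style=style, seed=seed,
        )

    if violation_kind == "inconsistent_scale":
        style, step = _sample_style(rng, percent_ok=False)
        pre = int(rng.integers(2, 4))
        post = int(rng.integers(2, 4))
        mult = float(rng.choice([5, 8, 10, 20]))
        restart = pre * step * mult
        post_step = step * float(rng.choice([1, 2, 5]))
        n_ticks = pre + post
        vmax = restart + (post - 1) * post_step
        return ChartSpec(
            n_bars=n_bars,
            bar_values=_sample_bars(rng, n_bars, 0.0, vmax),
            baseline_value=0.0, tick_step=step, n_ticks=n_ticks,
            scale_kind="broken", violation_kind="inconsistent_scale",
            break_segment=(restart, post_step), break_pre_ticks=pre,
            style=style, seed=seed,
        )

    if violation_kind == "nonzero_baseline":
        style, step = _sample_style(rng, percent_ok=True)
        n_ticks = int(rng.integers(4, 8))
        k0 = int(rng.integers(1, 9))
        if style.percent:
            # keep the top tick at or below 100%
            step = 10.0
            k0 = int(rng.integers(1, 11 - (n_ticks - 1)))
        baseline = k0 * step
        vmax = baseline + (n_ticks - 1) * step
        return ChartSpec(
            n_bars=n_bars,
            bar_values=_sample_bars(rng, n_bars, baseline, vmax),
            baseline_value=baseline, tick_step=step, n_ticks=n_ticks,
            scale_kind="linear", violation_kind="nonzero_baseline",
            style=style, seed=seed,
        )

    if violation_kind != "none":
        raise ValueError(f"violation_kind: unknown value {violation_kind!r}")

    style, step = _sample_style(rng, percent_ok=True)
    n_ticks = int(rng.integers(4, 8))
    if style.percent:
        step = float(rng.choice([10, 20, 25]))
        while (n_ticks - 1) * step > 100:
            n_ticks -= 1
    vmax = (n_ticks - 1) * step
    return ChartSpec(
        n_bars=n_bars,
        bar_values=_sample_bars(rng, n_bars, 0.0, vmax),
        baseline_value=0.0, tick_step=step, n_ticks=n_ticks,
        scale_kind="linear", violation_kind="none",
        style=style, seed=seed,
    )


def sample_corpus(
    n: int,
    violation_rate: float,
    mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    log_fraction: float = 0.12,
) -> list[ChartSpec]:
    """Draw ``n`` chart specs with i.i.d. Bernoulli(violation_rate) labels."""
    if n <= 0:
        raise ValueError("n: must be positive")
    if not (0 <= violation_rate <= 1):
        raise ValueError("violation_rate: must be in [0, 1]")
    mix = dict(mix or DEFAULT_VIOLATION_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mix: per-kind weights must sum to 1")
    kinds = sorted(mix)
    weights = np.array([mix[k] for k in kinds])
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        if rng.random() < violation_rate:
            kind = kinds[int(rng.choice(len(kinds), p=weights))]
        else:
            kind = "none"
        specs.append(sample_spec(rng, kind, log_fraction=log_fraction))
    return specs


# ---------------------------------------------------------------------------
# Corpus on disk

@dataclass
class ManifestRecord:
    image: str
    label: str
    sub_reason: str
    text_boxes: list[dict]
    tick_values: list[list]
    baseline_row: Optional[int]
    spec_id: str


@dataclass
class CorpusManifest:
    records: list[ManifestRecord]
    seed: int
    violation_rate: float

    def save(self, out_dir: Path) -> Path:
        out_dir = Path(out_dir)
        path = out_dir / "manifest.jsonl"
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(asdict(rec), sort_keys=True) + "\n")
        meta = {"seed": self.seed, "violation_rate": self.violation_rate}
        with open(out_dir / "corpus_meta.json", "w") as fh:
            json.dump(meta, fh, sort_keys=True)
        return path

    @classmethod
    def load(cls, out_dir: Path) -> "CorpusManifest":
        out_dir = Path(out_dir)
        records = []
        with open(out_dir / "manifest.jsonl") as fh:
            for line in fh:
                d = json.loads(line)
                records.append(ManifestRecord(**d))
        with open(out_dir / "corpus_meta.json") as fh:
            meta = json.load(fh)
        return cls(records=records, seed=meta["seed"], violation_rate=meta["violation_rate"])


def ground_truth_record(image_name: str, spec_id: str, gt: GroundTruth) -> ManifestRecord:
    return ManifestRecord(
        image=image_name,
        label=gt.violation_label.label,
        sub_reason=gt.violation_label.sub_reason,
        text_boxes=[
            {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1, "text": b.text, "role": b.role}
            for b in gt.text_boxes
        ],
        tick_values=[[r, v] for r, v in gt.tick_values],
        baseline_row=gt.baseline_row,
        spec_id=spec_id,
    )


def generate_corpus(
    n: int,
    violation_rate: float,
    mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    out_dir: Path = Path("corpus"),
    log_fraction: float = 0.12,
) -> CorpusManifest:
    """Render ``n`` charts to ``out_dir`` and write a JSON Lines manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = sample_corpus(n, violation_rate, mix=mix, seed=seed, log_fraction=log_fraction)
    records = []
    for i, spec in enumerate(specs):
        spec_id = f"chart-{i:05d}"
        img, gt = generate_chart(spec)
        name = f"{spec_id}.png"
        img.save(out_dir / name)
        records.append(ground_truth_record(name, spec_id, gt))
    manifest = CorpusManifest(records=records, seed=seed, violation_rate=violation_rate)
    manifest.save(out_dir)
    return manifest


def compose_compound(
    images: Sequence[Image.Image],
    layout: tuple[int, int],
    gutter_px: int = 10,
) -> tuple[Image.Image, list[tuple[int, int, int, int]]]:
    """Tile charts into a compound figure; the inverse of panel splitting.

    Returns the composite raster and the exact placement boxes.
    """
    rows, cols = layout
    if len(images) < 2:
        raise ValueError("images: need at least 2 panels for a compound figure")
    if gutter_px < 4:
        raise ValueError("gutter_px: must be >= 4")
    if rows * cols < len(images):
        raise ValueError("layout: capacity smaller than the number of images")
    cell_w = max(im.width for im in images)
    cell_h = max(im.height for im in images)
    W = cols * cell_w + (cols - 1) * gutter_px
    H = rows * cell_h + (rows - 1) * gutter_px
    canvas = Image.new("RGB", (W, H), BACKGROUND)
    bounds = []
    for i, im in enumerate(images):
        r, c = divmod(i, cols)
        x0 = c * (cell_w + gutter_px)
        y0 = r * (cell_h + gutter_px)
        canvas.paste(im, (x0, y0))
        bounds.append((x0, y0, x0 + im.width, y0 + im.height))
    return canvas, bounds
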