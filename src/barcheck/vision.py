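"""Chart parsing: panel splitting, text localization, recognition, roles, axes.

The published detection pipelines in this field use fine-tuned neural
models for localization and role prediction.  Here those stages are
classical computer-vision implementations behind the same interfaces
(stroke-width-filtered connected components, geometric role rules), plus
an *oracle* recognition backend that reads the generator's ground truth --
optionally corrupted by seeded character-confusion noise and tick-row
jitter -- so that the downstream feature and classifier stages can be
studied under controlled parsing error.

Pixel convention: origin top-left, rows grow downward, boxes are half-open
``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .chartgen import GroundTruth

__all__ = [
    "TextBox",
    "AxisModel",
    "UnprocessableChartError",
    "BackendUnavailableError",
    "split_compound",
    "localize_text",
    "recognize_text",
    "classify_text_roles",
    "detect_axes",
    "oracle_parse",
    "corrupt_text",
    "box_iou",
]

ROLES = ("y_tick", "x_tick", "y_title", "x_title", "title", "legend", "other", "unassigned")


class UnprocessableChartError(RuntimeError):
    """The chart cannot be reduced to an axis model (mirrors the attrition
    real pipelines see on low-quality figures)."""


class BackendUnavailableError(RuntimeError):
    """A requested external OCR backend is not installed."""


@dataclass
class TextBox:
    bounds: tuple[int, int, int, int]
    text: str = ""
    ocr_confidence: float = 0.0
    text_probability: float = 0.0
    role: str = "unassigned"

    def __post_init__(self):
        x0, y0, x1, y1 = self.bounds
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"bounds: degenerate box {self.bounds}")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bounds
        return ((x0 + x1) / 2, (y0 + y1) / 2)

    @property
    def width(self) -> int:
        return self.bounds[2] - self.bounds[0]

    @property
    def height(self) -> int:
        return self.bounds[3] - self.bounds[1]


@dataclass
class AxisModel:
    """Reconstructed y-axis: tick rows paired with parsed label values."""

    y_axis_col: int
    baseline_row: Optional[int]
    # (pixel row, parsed value or None on parse failure, source box)
    ticks: list[tuple[int, Optional[float], Optional[TextBox]]]
    detected_fraction: float = 1.0

    def parsed_ticks(self) -> list[tuple[int, float]]:
        out = [(r, v) for r, v, _ in self.ticks if v is not None]
        out.sort(key=lambda t: t[1])
        return out


def box_iou(a: Sequence[int], b: Sequence[int]) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    inter = (ix1 - ix0) * (iy1 - iy0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def _rgb(image: Image.Image) -> np.ndarray:
    return np.asarray(image.convert("RGB"), dtype=np.int16)


def _text_ink(a: np.ndarray) -> np.ndarray:
    """Achromatic dark pixels: glyphs and axis lines, not colored bars.

    The threshold keeps the antialiased halo of small glyphs so that they
    stay connected, while light grid lines remain background.
    """
    gray = a.mean(axis=2)
    chroma = a.max(axis=2) - a.min(axis=2)
    return (gray < 180) & (chroma < 60)


def _any_ink(a: np.ndarray) -> np.ndarray:
    return a.min(axis=2) < 245


# ---------------------------------------------------------------------------
# Compound figure separation

def _background_runs(has_ink: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Interior runs of all-background positions of length >= min_len."""
    runs = []
    n = len(has_ink)
    i = 0
    while i < n:
        if not has_ink[i]:
            j = i
            while j < n and not has_ink[j]:
                j += 1
            if i > 0 and j < n and (j - i) >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _ink_bbox(mask: np.ndarray) -> Optional[tuple[int, int, int, int]]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    return (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def split_compound(
    image: Image.Image,
    min_gutter: int = 4,
    min_panel: int = 60,
) -> list[tuple[Image.Image, tuple[int, int, int, int]]]:
    """Recursively cut the raster at background-only gutters.

    A cut is accepted only when every resulting segment contains an ink
    region at least ``min_panel`` px in both dimensions, which stops the
    splitter from shaving off titles or axis-label strips of a single
    chart.  Detected boxes extend to the gutter midlines, so they cover
    each panel together with its share of surrounding background.  A
    single-panel (or blank) image comes back as one full-image box.
    """
    a = _rgb(image)
    ink = _any_ink(a)
    text = _text_ink(a)
    boxes = _split_box(ink, text, (0, 0, image.width, image.height), min_gutter, min_panel)
    return [(image.crop(b), b) for b in boxes]


def _split_box(ink, text, box, min_gutter, min_panel, depth=0):
    x0, y0, x1, y1 = box
    sub = ink[y0:y1, x0:x1]
    sub_text = text[y0:y1, x0:x1]
    if not sub.any() or depth > 4:
        return [box]

    for axis in (0, 1):  # 0: horizontal cuts (rows), 1: vertical cuts (cols)
        profile = sub.any(axis=1 - axis)
        runs = _background_runs(profile, min_gutter)
        if not runs:
            continue
        # Panel gutters dwarf the incidental background bands inside a
        # chart (between labels and axes); only near-widest runs are
        # treated as candidate gutters.
        widest = max(hi - lo for lo, hi in runs)
        runs = [(lo, hi) for lo, hi in runs if (hi - lo) >= 0.45 * widest]
        cuts = sorted((lo + hi) // 2 for lo, hi in runs)
        cuts = _prune_cuts(sub, sub_text, axis, cuts, min_panel)
        if not cuts:
            continue
        segments = _segments_from_cuts(cuts, len(profile))
        out = []
        for lo, hi in segments:
            child = (x0, y0 + lo, x1, y0 + hi) if axis == 0 else (x0 + lo, y0, x0 + hi, y1)
            out.extend(_split_box(ink, text, child, min_gutter, min_panel, depth + 1))
        return out
    return [box]


def _segments_from_cuts(cuts: list[int], length: int) -> list[tuple[int, int]]:
    edges = [0] + list(cuts) + [length]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _prune_cuts(sub, sub_text, axis, cuts, min_panel, min_text_px=30):
    """Drop cuts until every segment looks like a panel: an ink region of
    panel size in both dimensions that also contains text ink (a bare bar
    sticking out of a cropped chart is not a panel)."""
    cuts = list(cuts)
    while cuts:
        segments = _segments_from_cuts(cuts, sub.shape[0] if axis == 0 else sub.shape[1])
        bad = None
        for k, (lo, hi) in enumerate(segments):
            piece = sub[lo:hi, :] if axis == 0 else sub[:, lo:hi]
            piece_text = sub_text[lo:hi, :] if axis == 0 else sub_text[:, lo:hi]
            bb = _ink_bbox(piece)
            tb = _ink_bbox(piece_text)
            if (
                bb is None
                or tb is None
                or (bb[2] - bb[0]) < min_panel
                or (bb[3] - bb[1]) < min_panel
                or int(piece_text.sum()) < min_text_px
                # text must be distributed over the panel (titles at the
                # top, tick labels along the axes); a stray bar crossed by
                # one text line is not a panel
                or (tb[2] - tb[0]) < 0.45 * (bb[2] - bb[0])
                or (tb[3] - tb[1]) < 0.45 * (bb[3] - bb[1])
            ):
                bad = k
                break
        if bad is None:
            return cuts
        # merge the offending segment with a neighbour by removing a cut
        drop = bad if bad < len(cuts) else len(cuts) - 1
        cuts.pop(drop)
    return cuts


# ---------------------------------------------------------------------------
# Text localization

def localize_text(
    image: Image.Image,
    max_glyph_height: int = 40,
    max_glyph_width: int = 60,
) -> list[TextBox]:
    """Stroke-width-filtered connected components merged into text lines.

    Each candidate box carries ``text_probability`` computed from
    stroke-width statistics (glyph strokes are thin and uniform) and an
    aspect plausibility term.  Roles are left unassigned and no text is
    recognized here.
    """
    a = _rgb(image)
    mask = _text_ink(a)
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)
    slices = ndimage.find_objects(labels)

    comps = []
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if h > max_glyph_height or w > max_glyph_width:
            continue  # axis lines, large rules
        comp_mask = labels[sl] == idx
        edt = ndimage.distance_transform_edt(comp_mask)
        sw = edt[comp_mask]
        sw_mean = 2.0 * float(sw.mean())
        sw_cv = float(sw.std() / (sw.mean() + 1e-9))
        comps.append(
            {
                "box": [sl[1].start, sl[0].start, sl[1].stop, sl[0].stop],
                "sw_mean": sw_mean,
                "sw_cv": sw_cv,
                # flat slivers are usually tick marks, but can also be the
                # detached bottom bar of a small digit -- they are kept for
                # the vertical merge pass and discarded only if still alone
                "sliver": h <= 2 and w <= 6,
            }
        )
    if not comps:
        return []

    merged = _merge_components(comps)
    W, H = image.size
    out = []
    for m in merged:
        x0, y0, x1, y1 = m["box"]
        # one-pixel pad reclaims the faint antialiased rim of each glyph
        x0, y0 = max(0, x0 - 1), max(0, y0 - 1)
        x1, y1 = min(W, x1 + 1), min(H, y1 + 1)
        sw_mean = float(np.mean([c["sw_mean"] for c in m["members"]]))
        sw_cv = float(np.mean([c["sw_cv"] for c in m["members"]]))
        # Glyph strokes at chart font sizes are ~1-4 px wide with a stable
        # width along the stroke; wide or erratic strokes are penalized.
        p = np.exp(-((sw_mean - 2.2) ** 2) / 10.0) * np.exp(-max(0.0, sw_cv - 0.6))
        h, w = y1 - y0, x1 - x0
        if h > 25 and w > 25:
            p *= 0.5  # blocky region, unlikely a text line
        out.append(
            TextBox(bounds=(x0, y0, x1, y1), text_probability=float(np.clip(p, 0.02, 1.0)))
        )
    out.sort(key=lambda b: (b.bounds[1], b.bounds[0]))
    return out


def _merge_components(comps: list[dict]) -> list[dict]:
    """Union-find merge: first along horizontal text lines (slivers
    excluded so tick marks do not glue onto labels), then along vertical
    stacks (rotated axis titles, split glyphs).  Slivers that never merged
    are discarded."""
    items = [{"box": list(c["box"]), "members": [c]} for c in comps]

    def try_merge(horizontal: bool):
        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(items):
                j = i + 1
                while j < len(items):
                    if horizontal and (
                        all(c["sliver"] for c in items[i]["members"])
                        or all(c["sliver"] for c in items[j]["members"])
                    ):
                        j += 1
                        continue
                    if _should_merge(items[i]["box"], items[j]["box"], horizontal):
                        bi, bj = items[i]["box"], items[j]["box"]
                        items[i]["box"] = [
                            min(bi[0], bj[0]), min(bi[1], bj[1]),
                            max(bi[2], bj[2]), max(bi[3], bj[3]),
                        ]
                        items[i]["members"].extend(items[j]["members"])
                        items.pop(j)
                        changed = True
                    else:
                        j += 1
                i += 1

    try_merge(horizontal=True)
    try_merge(horizontal=False)
    return [m for m in items if not all(c["sliver"] for c in m["members"])]


def _should_merge(a: list[int], b: list[int], horizontal: bool) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if horizontal:
        overlap = min(ay1, by1) - max(ay0, by0)
        min_h = min(ay1 - ay0, by1 - by0)
        if overlap < 0.5 * min_h:
            return False
        gap = max(ax0, bx0) - min(ax1, bx1)
        return gap <= max(5, 0.9 * max(ay1 - ay0, by1 - by0))
    # Vertical merging serves two purposes: stacked glyphs of rotated
    # text, and reuniting fragments of one small glyph.  A width-ratio
    # guard keeps a lone category letter from fusing with the axis title
    # below it, but touching fragments merge unconditionally.
    overlap = min(ax1, bx1) - max(ax0, bx0)
    wa, wb = ax1 - ax0, bx1 - bx0
    if overlap < 0.5 * min(wa, wb):
        return False
    if (ay1 - ay0) > 25 or (by1 - by0) > 25:
        return False
    gap = max(ay0, by0) - min(ay1, by1)
    if gap > 3 and min(wa, wb) < 0.4 * max(wa, wb):
        return False
    return gap <= max(4, 1.0 * max(wa, wb))


# ---------------------------------------------------------------------------
# Text recognition

# OCR-style confusions: visually similar glyph substitutions.
_CONFUSIONS = {
    "0": "O", "1": "l", "2": "Z", "3": "8", "4": "A", "5": "S",
    "6": "b", "7": "T", "8": "3", "9": "g", ".": ",", ",": ".",
    "%": "X", "-": "_",
}
_FALLBACK = "abcdefghijklmnopqrstuvwxyz"


def corrupt_text(text: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each character independently with probability ``rate``.

    Returns the corrupted string and the number of substitutions.
    """
    if rate <= 0:
        return text, 0
    chars = list(text)
    n_sub = 0
    for i, ch in enumerate(chars):
        if rng.random() < rate:
            chars[i] = _CONFUSIONS.get(ch, _FALLBACK[int(rng.integers(len(_FALLBACK)))])
            n_sub += 1
    return "".join(chars), n_sub


def _oracle_confidence(n_ok: int, n_bad: int, rng: np.random.Generator) -> float:
    """Simulated OCR confidence: high for clean characters, low for
    confused ones, so confidence correlates with error as it does for a
    real recognizer."""
    parts = []
    if n_ok:
        parts.append(n_ok * float(np.clip(rng.normal(0.97, 0.02), 0.0, 1.0)))
    if n_bad:
        parts.append(n_bad * float(rng.uniform(0.3, 0.7)))
    total = n_ok + n_bad
    return sum(parts) / total if total else 0.0


def recognize_text(
    image: Image.Image,
    boxes: Sequence[TextBox],
    backend: str = "oracle",
    ground_truth: Optional["GroundTruth"] = None,
    confusion_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[TextBox]:
    """Fill ``text`` and ``ocr_confidence`` on localized boxes.

    ``oracle`` copies ground-truth strings for boxes that overlap an
    annotated box at IoU >= 0.5 (optionally corrupted at a seeded
    character-confusion rate); ``tesseract`` delegates to pytesseract and
    fails loudly when the package is absent.  Boxes outside the image are
    skipped and reported via a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    W, H = image.size
    kept, skipped = [], []
    for b in boxes:
        x0, y0, x1, y1 = b.bounds
        if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
            skipped.append(b)
        else:
            kept.append(b)
    if skipped:
        warnings.warn(f"recognize_text: skipped {len(skipped)} box(es) outside image bounds")

    if backend == "oracle":
        if ground_truth is None:
            raise ValueError("oracle backend requires ground_truth")
        out = []
        for b in kept:
            best, best_iou = None, 0.0
            for g in ground_truth.text_boxes:
                iou = box_iou(b.bounds, g.bounds)
                if iou > best_iou:
                    best, best_iou = g, iou
            if best is None or best_iou < 0.5:
                out.append(replace(b, text="", ocr_confidence=0.0))
                continue
            text, n_bad = corrupt_text(best.text, confusion_rate, rng)
            conf = _oracle_confidence(len(text) - n_bad, n_bad, rng) if confusion_rate > 0 else 1.0
            out.append(replace(b, text=text, ocr_confidence=conf))
        return out

    if backend == "tesseract":
        try:
            import pytesseract  # noqa: F401
        except ImportError as err:
            raise BackendUnavailableError(
                "tesseract backend requested but pytesseract is not installed"
            ) from err
        out = []
        for b in kept:
            x0, y0, x1, y1 = b.bounds
            pad = 2
            crop = image.crop((max(0, x0 - pad), max(0, y0 - pad), min(W, x1 + pad), min(H, y1 + pad)))
            data = pytesseract.image_to_data(crop, config="--psm 7", output_type=pytesseract.Output.DICT)
            words = [(t, c) for t, c in zip(data["text"], data["conf"]) if t.strip()]
            text = " ".join(t for t, _ in words)
            conf = float(np.mean([c for _, c in words]) / 100.0) if words else 0.0
            out.append(replace(b, text=text, ocr_confidence=float(np.clip(conf, 0, 1))))
        return out

    raise ValueError(f"backend: unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# Text role classification

def classify_text_roles(boxes: Sequence[TextBox], image_dims: tuple[int, int]) -> list[TextBox]:
    """Assign roles from geometry alone.

    Numeric boxes whose right edges align into a vertical column on the
    left side become y-ticks; a bottom row of boxes becomes x-ticks; the
    topmost centered box is the title; a tall thin box hugging the left
    edge is the y-axis title.  Unassignable boxes keep role ``other``.
    """
    from .features import try_parse_numeric_label

    W, H = image_dims
    boxes = [replace(b) for b in boxes]
    for b in boxes:
        b.role = "other"

    # y-ticks: the largest right-edge-aligned column of numeric boxes in
    # the left 45% of the chart.
    numeric = [b for b in boxes if try_parse_numeric_label(b.text)[0] is not None]
    left_numeric = [b for b in numeric if b.center[0] < 0.45 * W]
    best_col: list[TextBox] = []
    for anchor in left_numeric:
        col = [b for b in left_numeric if abs(b.bounds[2] - anchor.bounds[2]) <= 6]
        if len(col) > len(best_col):
            best_col = col
    if len(best_col) >= 2:
        for b in best_col:
            b.role = "y_tick"
        # Non-numeric boxes aligned with the column are tick labels whose
        # recognition failed (e.g. a label sliced through by a cropped
        # axis); they count as found-but-unparsed ticks.
        col_right = int(np.median([b.bounds[2] for b in best_col]))
        for b in boxes:
            if (
                b.role == "other"
                and b.center[0] < 0.45 * W
                and b.height <= 25
                and abs(b.bounds[2] - col_right) <= 6
            ):
                b.role = "y_tick"

    # Bottom strip: an aligned row of boxes = x-ticks; a lone centered box
    # below them = x-axis title.
    bottom = [b for b in boxes if b.role == "other" and b.center[1] > 0.8 * H]
    best_row: list[TextBox] = []
    for anchor in bottom:
        row = [b for b in bottom if abs(b.bounds[1] - anchor.bounds[1]) <= 4]
        if len(row) > len(best_row):
            best_row = row
    if len(best_row) >= 2:
        for b in best_row:
            b.role = "x_tick"
    row_bottom = max((b.bounds[3] for b in best_row), default=0)
    for b in bottom:
        if b.role == "other" and b.bounds[1] >= row_bottom and abs(b.center[0] - W / 2) < 0.3 * W:
            b.role = "x_title"

    # Title: topmost centered box in the top band.
    top_candidates = [
        b for b in boxes if b.role == "other" and b.bounds[1] < 0.12 * H and abs(b.center[0] - W / 2) < 0.3 * W
    ]
    if top_candidates:
        min(top_candidates, key=lambda b: b.bounds[1]).role = "title"

    # y-axis title: tall, thin, hugging the left edge.
    for b in boxes:
        if b.role == "other" and b.height > 1.5 * b.width and b.bounds[0] < 0.08 * W:
            b.role = "y_title"
    return boxes


# ---------------------------------------------------------------------------
# Axis reconstruction

def detect_axes(image: Image.Image, boxes: Sequence[TextBox]) -> AxisModel:
    """Locate the axis lines and pair y-tick labels with tick rows.

    The y-axis is the longest vertical achromatic dark run just right of
    the y-tick label column; the baseline is the longest horizontal run in
    the lower part of the chart (absent on partially hidden axes).  Raises
    :class:`UnprocessableChartError` when no y-tick labels are available.
    """
    from .features import parse_tick_labels

    yticks = [b for b in boxes if b.role == "y_tick"]
    if not yticks:
        raise UnprocessableChartError("no y-axis tick labels found")

    a = _rgb(image)
    ink = _text_ink(a)
    H, W = ink.shape

    x_right = max(b.bounds[2] for b in yticks)
    col_lo, col_hi = x_right, min(W, x_right + 40)
    best_col, best_run = col_lo, -1
    for c in range(col_lo, col_hi):
        run = _longest_run(ink[:, c])
        if run > best_run:
            best_col, best_run = c, run

    region = ink[:, best_col:]
    row_runs = np.array([_longest_run(region[r]) for r in range(H)])
    lower = np.arange(H) > 0.4 * H
    candidates = np.where(lower, row_runs, 0)
    baseline_row: Optional[int] = None
    if candidates.max() >= 0.4 * (W - best_col):
        baseline_row = int(candidates.argmax())

    values = parse_tick_labels([b.text for b in yticks])
    ticks = []
    for b, v in zip(yticks, values):
        ticks.append((int(round(b.center[1])), v, b))
    n_parsed = sum(1 for _, v, _ in ticks if v is not None)
    ticks.sort(key=lambda t: -t[0])
    return AxisModel(
        y_axis_col=int(best_col),
        baseline_row=baseline_row,
        ticks=ticks,
        detected_fraction=n_parsed / len(ticks),
    )


def _longest_run(line: np.ndarray) -> int:
    best = cur = 0
    for v in line:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Oracle parsing (ground truth -> axis model, with controllable noise)

def oracle_parse(
    gt: "GroundTruth",
    confusion_rate: float = 0.0,
    row_jitter_px: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AxisModel, list[TextBox]]:
    """Build an :class:`AxisModel` straight from ground truth.

    This is the noise-controlled stand-in for the pixel pipeline: strings
    may be corrupted at a character-confusion rate and tick rows jittered
    by up to ``row_jitter_px``, emulating localization and OCR error
    without any rasterization.
    """
    from .features import parse_tick_labels

    rng = rng if rng is not None else np.random.default_rng(0)
    noisy = confusion_rate > 0 or row_jitter_px > 0

    boxes: list[TextBox] = []
    tick_boxes: list[TextBox] = []
    tick_rows: list[int] = []
    for g in gt.text_boxes:
        text, n_bad = corrupt_text(g.text, confusion_rate, rng)
        conf = _oracle_confidence(len(text) - n_bad, n_bad, rng) if noisy else 1.0
        tp = float(np.clip(rng.normal(0.96, 0.03), 0.0, 1.0)) if noisy else 1.0
        box = TextBox(bounds=g.bounds, text=text, ocr_confidence=conf,
                      text_probability=tp, role=g.role)
        boxes.append(box)
        if g.role == "y_tick":
            row = (g.y0 + g.y1) // 2
            if row_jitter_px > 0:
                row += int(rng.integers(-row_jitter_px, row_jitter_px + 1))
            tick_boxes.append(box)
            tick_rows.append(row)

    if not tick_boxes:
        raise UnprocessableChartError("no y-axis tick labels in ground truth")

    values = parse_tick_labels([b.text for b in tick_boxes])
    ticks = [(r, v, b) for r, v, b in zip(tick_rows, values, tick_boxes)]
    ticks.sort(key=lambda t: -t[0])
    n_parsed = sum(1 for _, v, _ in ticks if v is not None)
    axis = AxisModel(
        y_axis_col=max(b.bounds[2] for b in tick_boxes) + 6,
        baseline_row=gt.baseline_row,
        ticks=ticks,
        detected_fraction=n_parsed / len(ticks),
    )
    return axis, boxes
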