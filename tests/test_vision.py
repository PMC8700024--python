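"""Parser contracts: splitting, localization, recognition, roles, axes."""

import numpy as np
import pytest
from PIL import Image

from barcheck import chartgen, vision
from barcheck.vision import (
    BackendUnavailableError,
    TextBox,
    UnprocessableChartError,
    box_iou,
    classify_text_roles,
    corrupt_text,
    detect_axes,
    localize_text,
    oracle_parse,
    recognize_text,
    split_compound,
)


def pixel_parse(img, gt):
    boxes = localize_text(img)
    boxes = recognize_text(img, boxes, backend="oracle", ground_truth=gt)
    return classify_text_roles(boxes, img.size)


class TestSplitCompound:
    def test_single_chart_returns_full_image_box(self, rendered_corpus):
        for _, img, _ in rendered_corpus[:20]:
            panels = split_compound(img)
            assert len(panels) == 1
            assert panels[0][1] == (0, 0, img.width, img.height)

    def test_blank_image_returns_one_box(self):
        blank = Image.new("RGB", (300, 200), (255, 255, 255))
        assert [b for _, b in split_compound(blank)] == [(0, 0, 300, 200)]

    @pytest.mark.parametrize("layout,n", [((2, 2), 4), ((1, 2), 2), ((2, 1), 2)])
    def test_compound_round_trip_recovers_panels(self, rendered_corpus, layout, n):
        imgs = [img for _, img, _ in rendered_corpus[:n]]
        comp, bounds = chartgen.compose_compound(imgs, layout, gutter_px=10)
        panels = split_compound(comp)
        assert len(panels) == n
        for gt_box in bounds:
            assert max(box_iou(gt_box, b) for _, b in panels) >= 0.9


class TestLocalizeText:
    def test_blank_raster_yields_no_boxes(self):
        assert localize_text(Image.new("RGB", (200, 100), (255, 255, 255))) == []

    def test_ground_truth_recall_on_corpus(self, rendered_corpus):
        """>= 90% of annotated text boxes are recovered at IoU >= 0.5."""
        total = matched = 0
        for _, img, gt in rendered_corpus:
            boxes = localize_text(img)
            for g in gt.text_boxes:
                total += 1
                if any(box_iou(b.bounds, g.bounds) >= 0.5 for b in boxes):
                    matched += 1
        assert matched / total >= 0.90

    def test_ytick_column_is_covered(self, rendered_corpus):
        for _, img, gt in rendered_corpus[:10]:
            boxes = localize_text(img)
            n_yticks = sum(1 for g in gt.text_boxes if g.role == "y_tick")
            col_max = max(g.x1 for g in gt.text_boxes if g.role == "y_tick")
            overlapping = [b for b in boxes if b.bounds[0] < col_max]
            assert len(overlapping) >= n_yticks

    def test_probabilities_bounded(self, rendered_corpus):
        _, img, _ = rendered_corpus[0]
        for b in localize_text(img):
            assert 0.0 <= b.text_probability <= 1.0


class TestRecognizeText:
    def test_oracle_copies_ground_truth_exactly_without_noise(self, rendered_corpus):
        _, img, gt = rendered_corpus[0]
        boxes = localize_text(img)
        boxes = recognize_text(img, boxes, backend="oracle", ground_truth=gt)
        texts = {b.text for b in boxes if b.text}
        assert {g.text for g in gt.text_boxes} <= texts
        assert all(b.ocr_confidence == 1.0 for b in boxes if b.text)

    def test_confusion_rate_is_binomial(self):
        """~2% of characters substituted over a large character sample."""
        rng = np.random.default_rng(77)
        text = "0123456789,.%" * 1000
        _, n_sub = corrupt_text(text, 0.02, rng)
        n = len(text)
        sd = np.sqrt(0.02 * 0.98 * n)
        assert abs(n_sub - 0.02 * n) <= 4 * sd

    def test_out_of_bounds_box_skipped_and_reported(self, rendered_corpus):
        _, img, gt = rendered_corpus[0]
        bad = TextBox(bounds=(-5, 10, 30, 20))
        with pytest.warns(UserWarning, match="outside image bounds"):
            out = recognize_text(img, [bad], backend="oracle", ground_truth=gt)
        assert out == []

    def test_missing_external_backend_fails_loudly(self, monkeypatch):
        import builtins

        real_import = builtins.__import__

        def no_pytesseract(name, *args, **kwargs):
            if name == "pytesseract":
                raise ImportError("pytesseract not installed")
            return real_import(name, *args, **kwargs)

        monkeypatch.setattr(builtins, "__import__", no_pytesseract)
        img = Image.new("RGB", (50, 50), (255, 255, 255))
        with pytest.raises(BackendUnavailableError):
            recognize_text(img, [], backend="tesseract")

    def test_unknown_backend_rejected(self):
        img = Image.new("RGB", (50, 50), (255, 255, 255))
        with pytest.raises(ValueError, match="backend"):
            recognize_text(img, [], backend="magic")


class TestClassifyRoles:
    def test_numeric_column_left_of_axis_is_yticks(self):
        boxes = [
            TextBox(bounds=(60, 380, 80, 392), text="0"),
            TextBox(bounds=(55, 280, 80, 292), text="20"),
            TextBox(bounds=(55, 180, 80, 192), text="40"),
        ]
        out = classify_text_roles(boxes, (640, 480))
        assert [b.role for b in out] == ["y_tick"] * 3

    def test_bottom_row_is_xticks(self):
        boxes = [
            TextBox(bounds=(60, 380, 80, 392), text="0"),
            TextBox(bounds=(55, 180, 80, 192), text="40"),
            TextBox(bounds=(150, 430, 170, 442), text="A"),
            TextBox(bounds=(350, 430, 370, 442), text="B"),
            TextBox(bounds=(550, 430, 570, 442), text="C"),
        ]
        out = classify_text_roles(boxes, (640, 480))
        roles = {b.text: b.role for b in out}
        assert roles["A"] == roles["B"] == roles["C"] == "x_tick"

    def test_role_assignment_deterministic(self, rendered_corpus):
        _, img, gt = rendered_corpus[1]
        boxes = localize_text(img)
        boxes = recognize_text(img, boxes, backend="oracle", ground_truth=gt)
        r1 = [b.role for b in classify_text_roles(boxes, img.size)]
        r2 = [b.role for b in classify_text_roles(boxes, img.size)]
        assert r1 == r2

    def test_ytick_precision_and_recall_on_corpus(self, rendered_corpus):
        """y-tick role precision and recall both >= 0.9 against ground truth."""
        tp = fp = fn = 0
        for _, img, gt in rendered_corpus:
            pred = [b for b in pixel_parse(img, gt) if b.role == "y_tick"]
            truth = [g for g in gt.text_boxes if g.role == "y_tick"]
            for b in pred:
                if any(box_iou(b.bounds, g.bounds) >= 0.5 for g in truth):
                    tp += 1
                else:
                    fp += 1
            for g in truth:
                if not any(box_iou(b.bounds, g.bounds) >= 0.5 for b in pred):
                    fn += 1
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9


class TestDetectAxes:
    def test_round_trip_reproduces_tick_values_exactly(self, rendered_corpus):
        """Full pixel pipeline recovers ground-truth tick values on every
        non-hidden chart of the corpus."""
        n = 0
        for spec, img, gt in rendered_corpus:
            if spec.violation_kind == "hidden_axis":
                continue
            axis = detect_axes(img, pixel_parse(img, gt))
            assert [v for _, v in axis.parsed_ticks()] == [v for _, v in gt.tick_values]
            assert abs(axis.baseline_row - gt.baseline_row) <= 2
            n += 1
        assert n > 100

    def test_hidden_axis_charts_lose_baseline_and_fraction(self, rendered_corpus):
        checked = 0
        for spec, img, gt in rendered_corpus:
            if spec.violation_kind != "hidden_axis":
                continue
            axis = detect_axes(img, pixel_parse(img, gt))
            assert axis.baseline_row is None
            assert axis.detected_fraction < 1.0
            assert min(v for _, v in axis.parsed_ticks()) > 0
            checked += 1
        assert checked > 0

    def test_no_ytick_labels_is_unprocessable(self):
        img = Image.new("RGB", (200, 200), (255, 255, 255))
        with pytest.raises(UnprocessableChartError):
            detect_axes(img, [])


class TestOracleParse:
    def test_noiseless_oracle_matches_ground_truth(self, rendered_corpus):
        _, _, gt = rendered_corpus[0]
        axis, boxes = oracle_parse(gt)
        assert [v for _, v in axis.parsed_ticks()] == [v for _, v in gt.tick_values]
        assert all(b.ocr_confidence == 1.0 for b in boxes)
        assert axis.detected_fraction == 1.0

    def test_jitter_moves_rows_at_most_by_bound(self, rendered_corpus):
        _, _, gt = rendered_corpus[0]
        rng = np.random.default_rng(4)
        axis, _ = oracle_parse(gt, row_jitter_px=2, rng=rng)
        truth_rows = sorted(r for r, _ in gt.tick_values)
        got_rows = sorted(r for r, v, _ in axis.ticks)
        assert all(abs(a - b) <= 2 for a, b in zip(truth_rows, got_rows))
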