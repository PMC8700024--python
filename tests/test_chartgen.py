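"""Generator contracts: determinism, label soundness, geometry, corpora."""

import json

import numpy as np
import pytest

from barcheck import chartgen
from barcheck.chartgen import (
    ChartSpec,
    ChartStyle,
    compose_compound,
    generate_chart,
    generate_corpus,
    plan_chart,
    sample_corpus,
    sample_spec,
    validate_spec,
)


def simple_spec(**overrides):
    base = dict(
        n_bars=3,
        bar_values=(10.0, 25.0, 40.0),
        baseline_value=0.0,
        tick_step=20.0,
        n_ticks=4,
        scale_kind="linear",
        violation_kind="none",
        style=ChartStyle(),
        seed=7,
    )
    base.update(overrides)
    return ChartSpec(**base)


def label_predicate(spec):
    """Independent re-derivation of the violation label from raw spec
    fields (no use of violation_kind)."""
    if spec.scale_kind == "broken":
        return ("violation", "inconsistent_scale")
    if spec.hidden_fraction > 0:
        return ("violation", "hidden_axis")
    if spec.scale_kind == "linear" and spec.baseline_value > 0:
        return ("violation", "nonzero_baseline")
    return ("other", "none")


class TestGenerateChart:
    def test_rendering_is_deterministic(self):
        spec = simple_spec()
        img1, _ = generate_chart(spec)
        img2, _ = generate_chart(spec)
        assert img1.tobytes() == img2.tobytes()

    def test_zero_baseline_linear_chart_is_conforming(self):
        _, gt = generate_chart(simple_spec())
        assert (gt.violation_label.label, gt.violation_label.sub_reason) == ("other", "none")
        assert gt.tick_values[0] == (gt.baseline_row, 0.0)

    def test_nonzero_baseline_is_a_violation(self):
        spec = simple_spec(
            baseline_value=50.0,
            bar_values=(60.0, 75.0, 100.0),
            violation_kind="nonzero_baseline",
        )
        _, gt = generate_chart(spec)
        assert gt.violation_label.sub_reason == "nonzero_baseline"
        assert gt.tick_values[0][1] == 50.0

    def test_log_scale_chart_is_not_a_violation(self):
        spec = simple_spec(
            baseline_value=1.0,
            tick_step=10.0,
            n_ticks=3,
            scale_kind="log",
            bar_values=(2.0, 30.0, 80.0),
        )
        _, gt = generate_chart(spec)
        assert gt.violation_label.label == "other"
        assert [v for _, v in gt.tick_values] == [1.0, 10.0, 100.0]

    def test_linear_tick_pixel_spacing_constant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            spec = sample_spec(rng, "none", log_fraction=0.0)
            gt = plan_chart(spec)
            rows = sorted(r for r, _ in gt.tick_values)
            gaps = np.diff(rows)
            assert gaps.max() - gaps.min() <= 2  # +-1 px rounding

    def test_label_soundness_against_independent_predicate(self):
        rng = np.random.default_rng(11)
        for spec in sample_corpus(150, violation_rate=0.5, seed=13):
            gt = plan_chart(spec)
            assert (gt.violation_label.label, gt.violation_label.sub_reason) == label_predicate(spec)

    def test_hidden_axis_chart_loses_baseline_and_low_ticks(self):
        rng = np.random.default_rng(5)
        spec = sample_spec(rng, "hidden_axis")
        img, gt = generate_chart(spec)
        assert gt.baseline_row is None
        assert img.height < chartgen.CANVAS_H
        assert min(v for _, v in gt.tick_values) > 0

    def test_every_ytick_box_has_a_tick_value(self):
        rng = np.random.default_rng(17)
        for kind in ("none", "nonzero_baseline", "inconsistent_scale", "hidden_axis"):
            gt = plan_chart(sample_spec(rng, kind))
            rows = {r for r, _ in gt.tick_values}
            for box in gt.text_boxes:
                if box.role == "y_tick":
                    center = (box.y0 + box.y1) // 2
                    assert any(abs(center - r) <= 2 for r in rows)


class TestValidateSpec:
    @pytest.mark.parametrize(
        "overrides, field_name",
        [
            (dict(tick_step=-5.0), "tick_step"),
            (dict(bar_values=(10.0, 25.0, 900.0)), "bar_values"),
            (dict(n_bars=2), "n_bars"),
            (dict(baseline_value=10.0), "violation_kind"),
            (dict(scale_kind="log", baseline_value=1.0, tick_step=1.0), "tick_step"),
            (dict(hidden_fraction=0.5), "hidden_fraction"),
        ],
    )
    def test_invalid_specs_name_the_offending_field(self, overrides, field_name):
        with pytest.raises(ValueError, match=field_name):
            validate_spec(simple_spec(**overrides))


class TestCorpus:
    def test_realized_violation_count_within_three_binomial_sd(self):
        specs = sample_corpus(1000, violation_rate=0.055, seed=7)
        count = sum(1 for s in specs if s.violation_kind != "none")
        assert 34 <= count <= 77  # 55 +- 3*sqrt(0.055*0.945*1000)

    def test_zero_rate_gives_zero_violations(self):
        specs = sample_corpus(100, violation_rate=0.0, seed=1)
        assert all(s.violation_kind == "none" for s in specs)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            sample_corpus(10, 0.5, mix={"nonzero_baseline": 0.4}, seed=0)

    def test_manifest_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(12, 0.3, seed=21, out_dir=d1)
        generate_corpus(12, 0.3, seed=21, out_dir=d2)
        assert (d1 / "manifest.jsonl").read_bytes() == (d2 / "manifest.jsonl").read_bytes()

    def test_manifest_round_trips_losslessly(self, tmp_path):
        manifest = generate_corpus(8, 0.4, seed=33, out_dir=tmp_path)
        reloaded = chartgen.CorpusManifest.load(tmp_path)
        assert reloaded == manifest
        for rec in reloaded.records:
            assert (tmp_path / rec.image).exists()
        # record schema is exactly the documented field set
        line = json.loads((tmp_path / "manifest.jsonl").read_text().splitlines()[0])
        assert set(line) == {
            "image", "label", "sub_reason", "text_boxes", "tick_values",
            "baseline_row", "spec_id",
        }


class TestComposeCompound:
    def _charts(self, n):
        rng = np.random.default_rng(9)
        return [generate_chart(sample_spec(rng, "none"))[0] for _ in range(n)]

    def test_two_by_two_bounds_disjoint_and_separated(self):
        comp, bounds = compose_compound(self._charts(4), (2, 2), gutter_px=10)
        assert len(bounds) == 4
        for i, a in enumerate(bounds):
            for b in bounds[i + 1 :]:
                dx = max(a[0], b[0]) - min(a[2], b[2])
                dy = max(a[1], b[1]) - min(a[3], b[3])
                assert max(dx, dy) >= 10  # separated by at least the gutter

    def test_single_image_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compose_compound(self._charts(1), (1, 1))

    def test_capacity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            compose_compound(self._charts(4), (1, 3))

    def test_small_gutter_rejected(self):
        with pytest.raises(ValueError, match="gutter"):
            compose_compound(self._charts(2), (1, 2), gutter_px=2)
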