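# Methods

## The detection problem

A bar chart encodes each value as the area of a shaded bar, so the reader's
visual comparison is only faithful when area is proportional to value.
Three constructions break that proportionality: a y-axis that starts above
zero, a y-axis whose scale changes partway (a "broken" axis), and an axis
whose lower portion is cropped or occluded so the true baseline is
invisible.  `barcheck` detects these *proportional-ink violations* in
raster images of bar charts.  Log-scale axes also break area/value
proportionality but are an accepted convention in scientific figures, so
they are explicitly exempted: the scale-consistency machinery recognizes a
constant ratio between neighbouring tick labels and suppresses the
violation call.

## Synthetic corpus

Published figure collections cannot be bundled with a package, so the
evaluation corpus is synthetic.  `chartgen` renders single bar charts (and
tiled compound figures) from a `ChartSpec` that fully determines the
raster — identical specs are bit-identical PNGs — and emits exhaustive
ground truth: every text element's pixel box, string and role; each
tick's pixel row and numeric value; the x-axis row; and the violation
label.

Default study conditions (used by the acceptance script and tests):

| parameter | default | rationale |
| --- | --- | --- |
| violation rate | 0.055 | matches the ~5% prevalence reported for open-access bar charts |
| violation mix | 50% non-zero baseline, 25% broken scale, 25% hidden axis | non-zero baselines are the dominant published failure mode |
| log-scale share of conforming charts | 0.12 | log axes are common but a minority in biomedical figures |
| canvas | 640 x 480 px, white | open-access figure dumps are low-resolution; small canvases stress the parser |
| typography | DejaVu Sans 8–16 px, 0–2 decimals, optional thousands separators, optional percent suffix, optional trailing-zero trimming | exercises the numeric label grammar |
| ticks | 4–7, "nice" steps matched to the decimal style | labels print exactly, so noiseless parses are exact |

Hidden axes are produced by cropping the bottom of a zero-baseline chart:
the x-axis and the lowest tick(s) disappear and the crop line slices
through the lowest remaining tick label, reproducing the partially hidden
axes seen in print.  Broken axes place both linear segments at uniform
tick spacing with a double-slash glyph at the jump — exactly the
distortion the rule targets.

What the generator does *not* emulate: photographic/microscopy content,
JPEG artifacts, skew, textured backgrounds, fonts other than DejaVu Sans,
overlapping annotation text, and non-bar chart types.  Passing tests
therefore demonstrate the correctness of the feature and decision
machinery under controlled parsing error, not field performance of the
classical localizer on arbitrary published figures.

## Chart parsing

The production systems this package mirrors use fine-tuned neural networks
for text localization and role prediction.  `vision` provides classical
stand-ins behind the same interfaces, so downstream stages are testable
without GPU training, plus an *oracle* backend that reads generator ground
truth directly with controllable corruption.

- **Panel splitting** projects ink density and cuts at background-only
  gutters.  A cut is accepted only when every segment contains a
  panel-sized ink region (≥ 60 px in both dimensions) whose achromatic
  "text ink" spreads over ≥ 45% of the region in both axes — this stops
  the splitter from shaving titles or label strips off a single chart and
  from splitting a cropped chart between its disconnected bars.  Detected
  boxes extend to gutter midlines.
- **Text localization** thresholds achromatic dark pixels (glyphs and axis
  lines; chromatic bar fills are excluded), labels connected components,
  filters out long axis lines, and merges fragments: first along
  horizontal text lines, then vertically (rotated axis titles, the
  detached pieces of small glyphs).  Each box's `text_probability` comes
  from stroke-width statistics (distance-transform based): glyph strokes
  are thin and uniform, so wide or erratic strokes are penalized.
- **Recognition** either copies ground-truth strings (oracle) or delegates
  to an external OCR engine; a missing engine raises, never silently
  falls back.  Oracle noise substitutes each character independently at a
  configurable rate using visually confusable glyphs (0→O, 5→S, .→,),
  and simulated confidence is high for clean characters and low for
  confused ones, as with a real recognizer.
- **Role assignment** is purely geometric: the largest right-edge-aligned
  column of numeric boxes on the left is the y-tick column (non-numeric
  boxes aligned with it count as found-but-unparsed ticks); an aligned
  bottom row is x-ticks; the topmost centered box is the title; a tall
  thin left-edge box is the y-axis title.
- **Axis reconstruction** finds the y-axis as the longest vertical dark
  run beside the tick column and the baseline as the longest horizontal
  run in the lower part (absent for hidden axes), then pairs tick boxes
  with rows at their vertical centers.  Charts without usable y-tick
  labels raise `UnprocessableChartError` and are excluded from prevalence
  denominators, mirroring the attrition real pipelines see.

## Features

Seven features summarize each parsed chart (plus one auxiliary flag):

- `f1` — value of the lowest y-axis label.  If the lowest parsed label
  sits more than 0.6 median tick spacings above the baseline (or the
  baseline is undetected), the arithmetic tick sequence is extrapolated
  down to the row nearest the baseline.  The 0.6 factor is below one full
  spacing (to catch a single hidden tick) and above 0.5 (to tolerate
  label-centering offset).
- `f2` — scale inconsistency: max over adjacent tick differences of
  |d − median(d)| / |median(d)|, computed in axis (pixel-row) order so a
  corrupted label that breaks monotonicity surfaces as a large value;
  capped at 50 to keep wild parses on a bounded scale.  Axes with fewer
  than three parsed ticks get f2 = 0 with a low-information flag.
- `f3` — whether `f1` was inferred rather than read.
- `f4` — whether the axis mixes integer- and decimal-formatted labels
  (a known OCR weak spot, and generated legitimately by trailing-zero
  trimming).
- `f5`, `f6` — mean localizer text probability and mean OCR confidence
  over the y-tick boxes: parsing-quality signals that let the classifier
  discount unreliable reconstructions.
- `f7` — bar-chart class probability (from a stub on synthetic data; the
  corpus is all bar charts, so it carries jitter but no signal).
- `log_flag` — adjacent tick ratios constant to within 2% while
  differences are inconsistent: a log axis, exempt from the rules.

The tolerance separating "one scale" from a broken scale is 0.02
(relative), chosen to absorb label rounding while catching every
generated break; it is exposed in configuration.  The numeric label
grammar accepts signs, well-formed comma grouping, decimals, exponents
and a trailing percent; percent is divided out only when *every* tick on
the axis carries it.

## Decisions

`rule_based_detect` encodes the rules with precedence hidden axis >
broken scale > non-zero baseline and the log exemption.  On noiseless
parses it reproduces generator labels exactly (asserted at corpus scale),
which is the round-trip soundness check: generator and rules implement
the same predicate through the full pipeline.

Under parsing noise rules are brittle, so the probabilistic detector is a
500-tree random forest (sqrt feature subsampling, unlimited depth, fixed
seed, unweighted classes by default) over f1–f7.  The fit canonically
sorts training rows, making it invariant to table row order.  The
decision threshold (default 0.5) is a user-facing dial: `threshold_sweep`
tabulates precision, recall, F1 and predicted prevalence across a grid,
which is how a conservative classifier's prevalence can be aligned with a
human-annotated rate (e.g. lowering toward ~0.23) at a known
false-positive cost.

## Evaluation protocol

Stratified 5-fold cross-validation refits the forest per fold and scores
held-out charts: ROC AUC (rank-based, ties half credit), precision and
recall at the stated threshold, F1.  Every aggregate reports both SD and
SE across folds, since conventions differ by metric.  Inter-annotator
agreement uses Cohen's kappa with marginal-product expected agreement.
Test oracles are independent routes: brute-force pair counting for AUC,
the direct agreement formula for kappa, and exhaustive hypergeometric
enumeration for the Fisher test.

## Study-level statistics

`prevalence(k, n)` reports k/n with the binomial standard error
sqrt(p(1−p)/n) — this convention reproduces the printed ±0.1% at
479/20,666 — rendering percentages to one decimal.  `fisher_exact` is the
two-sided probability-mass convention (summing hypergeometric point
probabilities ≤ the observed table's), the most common definition and the
one that matches the published within-career p-values 0.53 and 0.61.
`compare_feature_distributions` contrasts two feature tables per feature
(two-sample KS for continuous, absolute proportion difference for
boolean) to check that an unlabeled scoring corpus resembles the labeled
training corpus before predictions on it are trusted.

## Problem sizes and numerical notes

The acceptance evaluation uses 5,000 charts at a 5.5% violation rate with
2% character confusion and ±2 px tick-row jitter, cross-validated with
500 trees — about half a minute end to end.  The corpus for that route is
generated as ground-truth geometry without rasterization, since the
oracle backend consumes annotations, not pixels; the pixel pipeline is
exercised on a 200-chart rendered corpus in the test suite.  Degenerate
inputs are handled explicitly: undefined precision/recall return a
marker rather than 0, degenerate Fisher margins return p = 1 with a
warning, axes with fewer than two parsed ticks are unprocessable, and
kappa is undefined when expected agreement is 1.

## Known limitations

- The classical localizer and role rules are tuned to the generator's
  typography; on arbitrary published figures a trained detector should be
  plugged in through the same interfaces.
- The rule detector's hidden-axis clause requires a positive extrapolated
  baseline value; axes hidden in ways that leave a zero tick visible are
  not callable from these features.
- Chart-type classification is out of scope; `f7` comes from the manifest
  or a stub.
- Scores are used only through thresholds; no probability calibration is
  attempted.
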