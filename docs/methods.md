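# Methods

`cgmkit` is a desk-scale toolkit for studying how continuous glucose
monitoring (CGM) data is summarized: it generates synthetic
type-1-diabetes (T1D) cases with controllable glycemic quality, computes
the standard Ambulatory Glucose Profile (AGP) metrics and percentile
bands, produces deterministic rule-based clinical summaries of each case,
and scores graded summaries with a clinician rubric and chance-corrected
inter-rater agreement. This note records the models, the constants, and
the design decisions behind each stage.

## Patient model

The glucose dynamics are a Bergman minimal model driven by meal and
insulin inputs:

    dG/dt = -p1 (G - Gb) - X G + Ra(t)
    dX/dt = -p2 X + p3 (I(t) - Ib)

with `G` plasma glucose (mg/dL), `X` remote insulin action (1/min), and
`I` plasma insulin (µU/mL). Meal carbohydrate appearance uses a
two-compartment absorption cascade with a common rate `ka`, so a meal of
`c` grams at time 0 contributes `Ra(t) = f_carb · c · ka² · t · e^(-ka t)`.
Plasma insulin is `I(t) = dose_scale · Ib + ki · D(t)` where the
subcutaneous depot `D` absorbs boluses first-order at rate `ki`; every
unit of insulin delivery (basal and bolus) is multiplied by the single
calibration knob `dose_scale`.

Day-to-day variation in insulin requirements — the dominant real-world
source of T1D glycemic variability — is modeled as a per-day lognormal
multiplier on all insulin delivery with sigma `day_sens_sd` (default
0.2, i.e. roughly ±20 % day-to-day swings). This makes some days run
high and some low around the calibrated mean, and is what produces
occasional hypoglycemia in tightly controlled cases and the per-day
spread the variability analyzer reports.

Default parameters (one place: `PatientParams`):

| parameter | default | units | meaning |
|---|---|---|---|
| `Gb` | 110 | mg/dL | basal glucose |
| `p1` | 0.02 | 1/min | glucose effectiveness |
| `p2` | 0.028 | 1/min | insulin action decay |
| `p3` | 2.5e-5 | 1/min per µU/mL | insulin sensitivity gain |
| `Ib` | 15 | µU/mL | basal insulin |
| `ka` | 0.035 | 1/min | meal absorption rate |
| `f_carb` | 8.0 | mg/dL per g | carb-to-glucose scale |
| `ki` | 0.025 | 1/min | insulin absorption rate |
| `bolus_gain` | 1500 | µU/mL·min per U | plasma insulin exposure per unit |
| `day_sens_sd` | 0.2 | — | per-day insulin multiplier sigma |
| `dose_scale` | 1.0 | — | calibration knob, bounds [0.1, 10] |

Rates sit in the usual minimal-model ranges; `p3` is set high enough
that sweeping `dose_scale` across its bounds moves the realized Glucose
Management Indicator (GMI) well past the 6–9 % band the generated suites
target. With no meals and `dose_scale = 1` the state `(Gb, 0)` is an
exact equilibrium, which anchors the model's sanity tests.

### Numerical integration

The linear subsystems (meal cascade, insulin depot, insulin action) have
closed-form impulse responses and are evaluated exactly on the 1-minute
grid (the `X` filter uses a trapezoid discretization, second-order
accurate). The scalar glucose equation is integrated with an
exponential integrator: over each minute, `X` and `Ra` are frozen at
their midpoints, making the equation linear with decay rate `p1 + X`;
the update is then exact for the frozen inputs, unconditionally stable,
and keeps `G` positive (the decay rate cannot go negative because
`I(t) ≥ 0` bounds `X ≥ -(p3/p2)·Ib > -p1`). Against an adaptive
high-accuracy reference integration the trace agrees to well under
1 mg/dL except in the minutes straddling a bolus impulse (where the
1-minute grid smears the insulin step, costing ~2 mg/dL transiently) —
below the sensor's quantization either way.

## Sensor model

Interstitial sensing applies, in order: a first-order lag (time constant
`tau_lag`, default 10 min), sampling every `interval_min` (default 5 min,
288 readings/day), multiplicative AR(1) Gaussian noise
(`noise_cv` = 0.05, `ar_phi` = 0.7 — typical CGM error magnitude and
persistence), quantization to 1 mg/dL (real CGMs report integers; this
also makes CSV round-trips and reruns byte-exact), and clamping to the
reporting range [39, 401] mg/dL.

Missing data: per day, with probability 0.3, one contiguous gap of
uniform length 30–120 min is cut out. Gaps are cut, never imputed, and
every downstream consumer treats them as censored time.

## Reproducibility and calibration

Each case draws from named RNG substreams seeded
`default_rng([case_seed, k])` with `k` = 0 meals, 1 sensor noise, 2 gaps,
3 day-to-day sensitivity, so no feature's draws can silently shift
another's. Calibration fixes the meal/sensitivity realization, switches
noise off, and bisects `dose_scale` until the realized GMI (through the
full lag/sample/quantize/clamp sensor path) is within ±0.05 of target;
an unreachable target fails loudly, naming the achievable interval.
Suites space targets evenly across the requested GMI range with case
seeds `base_seed + 1 … base_seed + n`. Across seeds, the realized GMI
of every 14-day case lands within ±0.1 of its target including sensor
noise and gaps.

## Metrics

The ten AGP header metrics: days active (distinct calendar dates with a
reading), % captured (readings over `expected_days × 1440/interval`),
mean glucose, GMI, CV, and the five range percentages. Conventions,
fixed and recorded in every report:

- every percentage is a reading-count fraction of observed readings
  (gaps excluded from the denominator, no duration weighting);
- GMI = 3.31 + 0.02392 × mean glucose, the standard linear map onto the
  HbA1c scale; constants live in one config object;
- CV uses the population SD (the window is the whole observation, not a
  sample);
- boundaries: above 250 means g > 250; in range is 70 ≤ g ≤ 180; below
  70/54 are strict. Time above 180 is reported under two conventions:
  **cumulative** (g > 180; the clinical ground truth and the default) and
  **banded** ("level 1", 180 < g ≤ 250, i.e. 181–250 on integer
  readings). The banded figure plus time above 250 equals the cumulative
  figure exactly at the count level; exposing both lets an analysis
  diagnose the common mistake of reporting the level-1 band when the
  cumulative figure was requested.

## AGP bands

Readings pool across days into clock-time bins (default 60 min, 24
bins); percentiles 5/25/50/75/95 per bin use linear interpolation.
Empty bins are reported absent (NaN, count 0) and never interpolated, so
missing overnight data can't masquerade as normal glycemia. The
maximal-IQR window (p75 − p25) ties break to the earliest clock time,
keeping narratives deterministic.

## Episode detection

One scan over the regularized series: an episode opens once readings
beyond threshold have been sustained ≥ 15 min, absorbs in-range dips
shorter than 15 min, closes after ≥ 15 min back in range, and is
terminated (not extended) by any data gap > 30 min. Each reading is
credited one nominal interval, so four 5-minute readings constitute a
20-minute episode. Level 2 means a nadir < 54 mg/dL (hypo) or a peak
> 250 mg/dL (hyper); "prolonged" means ≥ 120 min; nocturnal means any
overlap with 00:00–06:00. These are the consensus event conventions; all
constants live in `SummaryRules`. The detector is property-tested
against an independent run-length-encoding oracle on randomized jagged
series with dropped readings and long gaps.

## Narratives

Each analyzer emits structured facts, ordered concern flags, and
candidate sentences with priorities; rendering keeps at most six, always
at least two, in fixed order — the same finding always renders the same
text. Guard rails, each encoding a way automated summaries go wrong:

- severity adjectives are threshold-gated (time above 180 ≤ 25 % with
  ≤ 2 % above 250 and no prolonged episodes is at most "mild");
- the word "stable" is forbidden whenever GMI ≥ 8 %, because low
  variability around a high mean is uniform hyperglycemia;
- nocturnal and level-2 hypoglycemia always surface regardless of count,
  and overnight readings in [70, 80) are reported as near-misses;
- absence claims ("no hypoglycemia") are qualified whenever the series
  has gaps — nothing is asserted about unrecorded time;
- the main-concern narrative always restates GMI and time in range.

The main concern is the first matching rule of: level-2 hypoglycemia or
time below 70 ≥ 4 % → hypoglycemia; any nocturnal episode → nocturnal
hypoglycemia; TIR < 70 % or GMI ≥ 8 % → hyperglycemia burden;
CV > 36 % → variability; otherwise the case meets targets. The order
encodes the clinical priority of hypoglycemia — especially nocturnal —
over everything else.

## Rubric scoring and agreement

Five yes/no rubric questions per case × task × rater: accuracy,
completeness, safety, patient suitability, clinician suitability.
Accuracy and the suitabilities score 1 for "yes"; completeness and
safety ask whether a flaw is present, so "yes" scores 0. Aggregation
requires a complete case × task × rater grid (override available),
reports per-rater totals and their mean — the mean-of-totals is the
headline "x / n cases" figure (per-case averaging first gives the same
number for a complete grid, but the choice is documented here).

Agreement uses Gwet's AC1 for two raters and binary answers:
`pa` the fraction of identical answers, `π` the mean prevalence across
raters, `pe = 2π(1−π)` and `AC1 = (pa − pe)/(1 − pe)`. Since `pe ≤ ½`
the denominator is never degenerate; AC1 = 1 exactly when agreement is
perfect, and unlike Cohen's kappa it does not collapse when one answer
dominates. The general multi-rater, multi-category AC1 is out of scope.

## What the generator does and does not emulate

It emulates: a realistic 5-minute interstitial signal with lag,
autocorrelated noise and quantization; meal/bolus structure with per-day
jitter; day-to-day insulin sensitivity swings; sensor gaps; and a
case spectrum whose realized GMI spans a prescribed range. It does not
emulate rescue-carbohydrate behavior after hypoglycemia,
compression-induced lows, calibration drift over a sensor's life,
sensor warm-up, or mmol/L devices. Consequently, passing tests show the
analytics are correct on plausibly structured data — not that the
simulator reproduces any particular physiological dataset, nor that the
narratives match what a clinician would write for a real patient.

## Problem sizes and tolerances

The default suite is 10 cases × 14 days at 5-minute sampling (4032
grid points per case); suite generation plus metrics runs in a few
seconds. Property suites use 100 randomized series for the metric and
episode oracles and 1000 random rating pairs for AC1. Unit tests use
1–3 day cases. Calibration tolerance is ±0.05 GMI points (≈2 mg/dL of
mean glucose), against an acceptance band of ±0.1 for realized GMI with
noise. Equilibrium drift must stay below 0.01 mg/dL over 24 h.

## Known limitations

The minimal model has no hepatic/renal saturation, exercise, stress, or
circadian insulin-sensitivity structure beyond the per-day multiplier;
boluses are carb-proportional with no corrections or stacking logic;
`dose_scale` moves basal and bolus together, so over-basalized and
over-bolused phenotypes are not distinguishable. Episode duration
credits one nominal interval per reading, which overstates duration by
up to one interval for sparse in-gap data. The AGP banding assumes the
series has been regularized to a grid; heavily jittered timestamps
should pass through `regularize` first.
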