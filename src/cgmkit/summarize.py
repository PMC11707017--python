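"""Rule-based reference implementations of the five AGP summarization tasks.

Each analyzer turns a CGM series (plus the AGP percentile bands where
relevant) into a :class:`Finding`: structured key-value evidence, an
ordered list of concern flags, and a deterministic 2-6 sentence template
narrative.  The five tasks are the standard AGP reading order: data
quality, hyperglycemia, hypoglycemia, glycemic variability, and the main
clinical concern.

The analyzers deliberately hard-code the guard rails a clinician applies
when reading an AGP:

* severity adjectives are threshold-gated — a case with a few percent of
  time above range is labelled "mild", never "notable";
* glucose control is never described with the word "stable" when the GMI
  is in the high range, however low the variability;
* nocturnal and level-2 hypoglycemia always surface in the narrative,
  regardless of how rare they are, and overnight near-misses (readings
  just above the hypoglycemic threshold) are reported;
* the main-concern narrative always restates GMI and time in range;
* absence-of-events claims are always qualified when the series has gaps
  (nothing is inferred across missing data).

Episode conventions follow the international consensus definitions: an
event is >= 15 min beyond threshold, closes after >= 15 min back in range,
level 2 means < 54 mg/dL (hypo) or > 250 mg/dL (hyper), and "prolonged"
means >= 120 min.  All constants live in :class:`SummaryRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agp import AGPBands, compute_bands, iqr_profile
from .io import GlucoseSeries
from .metrics import (
    MetricReport,
    cv as cv_metric,
    days_active,
    gmi as gmi_of_mean,
    mean_glucose,
    percent_captured,
    time_in_ranges,
)

TASKS = ("data_quality", "hyperglycemia", "hypoglycemia", "variability", "main_concern")


@dataclass(frozen=True)
class SummaryRules:
    """Every clinical constant used by the analyzers, in one place."""

    hypo_threshold: float = 70.0    # mg/dL, level-1 hypoglycemia
    hypo_level2: float = 54.0       # mg/dL
    hyper_threshold: float = 180.0  # mg/dL, level-1 hyperglycemia
    hyper_level2: float = 250.0     # mg/dL
    min_duration_min: float = 15.0  # minimum event duration
    end_recovery_min: float = 15.0  # in-range time that closes an event
    prolonged_min: float = 120.0    # "prolonged" episode cut
    censor_gap_min: float = 30.0    # data gap that terminates an open event
    nocturnal_start_min: int = 0    # 00:00
    nocturnal_end_min: int = 360    # 06:00
    near_miss_low: float = 70.0     # overnight near-miss band [low, high)
    near_miss_high: float = 80.0
    high_cv_pct: float = 36.0       # variability target
    min_pct_captured: float = 70.0  # data-quality verdict
    min_days_active: int = 10
    tir_target_pct: float = 70.0    # time-in-range target
    gmi_high_pct: float = 8.0       # GMI at/above which control is "high"
    tbr_concern_pct: float = 4.0    # time below 70 that makes hypo primary


DEFAULT_RULES = SummaryRules()


@dataclass(frozen=True)
class Episode:
    """One contiguous out-of-range excursion."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float
    extremum: float
    kind: str             # "hypo" | "hyper"
    level: int            # 1 or 2
    nocturnal: bool
    prolonged: bool


@dataclass(frozen=True)
class Finding:
    """Structured evidence plus rendered narrative for one task.

    ``sentences`` are (priority, text) candidates, lower priority number =
    more important; :func:`render_narrative` keeps at most six.
    """

    task: str
    facts: dict
    sentences: tuple = ()
    flags: tuple = ()
    narrative: str = ""

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "facts": self.facts,
            "flags": list(self.flags),
            "narrative": self.narrative,
        }


def _fmt(x) -> str:
    """Canonical number formatting shared by facts and narratives."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.1f}"


def _round(x) -> float:
    return float(round(float(x), 1))


def _clock(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


def _overlaps_nocturnal(start: pd.Timestamp, end: pd.Timestamp, rules: SummaryRules) -> bool:
    day = start.normalize()
    while day <= end.normalize():
        w0 = day + pd.Timedelta(minutes=rules.nocturnal_start_min)
        w1 = day + pd.Timedelta(minutes=rules.nocturnal_end_min)
        if start < w1 and end > w0:
            return True
        day += pd.Timedelta(days=1)
    return False


def detect_episodes(
    series: GlucoseSeries,
    threshold: float,
    direction: str,
    min_duration: float = DEFAULT_RULES.min_duration_min,
    end_recovery: float = DEFAULT_RULES.end_recovery_min,
    censor_gap_min: float = DEFAULT_RULES.censor_gap_min,
    level2_threshold: float | None = None,
    rules: SummaryRules = DEFAULT_RULES,
) -> list[Episode]:
    """One-pass scan for out-of-range episodes.

    An episode opens once readings beyond the threshold have been sustained
    for at least ``min_duration`` minutes, absorbs in-range dips shorter
    than ``end_recovery``, and closes after ``end_recovery`` minutes back in
    range.  Gaps longer than ``censor_gap_min`` terminate an open episode
    and reset any pending run: nothing is inferred across missing data.
    Each reading is credited one nominal interval of duration, so an
    episode's duration is (last out-of-range time - start) + interval.
    """
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    episodes: list[Episode] = []
    if len(series) == 0:
        return episodes
    interval = float(series.nominal_interval)
    times = series.timestamps
    minutes = times.asi8 / 60e9
    values = series.values
    is_out = values < threshold if direction == "below" else values > threshold

    pend_start = pend_start_t = pend_ext = None
    ep = None  # dict(start, start_t, last_out, last_out_t, ext)
    recov_t = None

    def close(ep):
        start = times[ep["start"]]
        end = times[ep["last_out"]] + pd.Timedelta(minutes=interval)
        dur = (ep["last_out_t"] - ep["start_t"]) + interval
        ext = ep["ext"]
        if level2_threshold is None:
            level = 1
        elif direction == "below":
            level = 2 if ext < level2_threshold else 1
        else:
            level = 2 if ext > level2_threshold else 1
        episodes.append(Episode(
            start=start, end=end, duration_min=dur, extremum=ext,
            kind="hypo" if direction == "below" else "hyper", level=level,
            nocturnal=_overlaps_nocturnal(start, end, rules),
            prolonged=dur >= rules.prolonged_min,
        ))

    prev_t = None
    for i in range(len(values)):
        t, v, out = minutes[i], values[i], bool(is_out[i])
        if prev_t is not None and t - prev_t > censor_gap_min:
            if ep is not None:
                close(ep)
                ep = None
            pend_start = None
            recov_t = None
        prev_t = t
        if ep is not None:
            if out:
                ep["last_out"], ep["last_out_t"] = i, t
                ep["ext"] = min(ep["ext"], v) if direction == "below" else max(ep["ext"], v)
                recov_t = None
            else:
                if recov_t is None:
                    recov_t = t
                if (t - recov_t) + interval >= end_recovery:
                    close(ep)
                    ep = None
                    recov_t = None
        elif out:
            if pend_start is None:
                pend_start, pend_start_t, pend_ext = i, t, v
            else:
                pend_ext = min(pend_ext, v) if direction == "below" else max(pend_ext, v)
            if (t - pend_start_t) + interval >= min_duration:
                ep = {"start": pend_start, "start_t": pend_start_t,
                      "last_out": i, "last_out_t": t, "ext": pend_ext}
                pend_start = None
                recov_t = None
        else:
            pend_start = None
    if ep is not None:
        close(ep)
    return episodes


def render_narrative(finding: Finding) -> str:
    """Deterministic template fill: keep at most six candidate sentences in
    priority order (lowest number first, stable on ties)."""
    ranked = sorted(enumerate(finding.sentences), key=lambda p: (p[1][0], p[0]))
    chosen = sorted(i for i, _ in ranked[:6])
    return " ".join(finding.sentences[i][1] for i in chosen)


def _finish(task, facts, sentences, flags) -> Finding:
    f = Finding(task=task, facts=facts, sentences=tuple(sentences), flags=tuple(flags))
    return Finding(task=task, facts=facts, sentences=tuple(sentences),
                   flags=tuple(flags), narrative=render_narrative(f))


def _gap_facts(series: GlucoseSeries) -> tuple[int, float]:
    gaps = series.gaps()
    total = sum((b - a).total_seconds() / 60.0 - series.nominal_interval for a, b in gaps)
    return len(gaps), _round(total)


def _absence_sentence(what: str, n_gaps: int, gap_minutes: float) -> str:
    """Absence claim, censored for gaps: never asserts what happened during
    missing data."""
    if n_gaps:
        return (f"No {what} was detected in the recorded data, but {n_gaps} sensor "
                f"gap(s) totalling {_fmt(gap_minutes)} minutes could not be assessed.")
    return f"No {what} was detected."


def assess_data_quality(
    series: GlucoseSeries,
    expected_days: int = 14,
    rules: SummaryRules = DEFAULT_RULES,
) -> Finding:
    """Verdict on whether the capture is sufficient to interpret: good iff
    percent captured >= 70 and at least 10 of the expected days have data."""
    days = days_active(series)
    pct = _round(percent_captured(series, expected_days))
    n_gaps, gap_min = _gap_facts(series)
    good = pct >= rules.min_pct_captured and days >= rules.min_days_active
    facts = {
        "days_active": days, "expected_days": expected_days, "pct_captured": pct,
        "n_gaps": n_gaps, "gap_minutes": gap_min,
        "verdict": "good" if good else "insufficient",
        "thresholds": {"min_pct_captured": rules.min_pct_captured,
                       "min_days_active": rules.min_days_active},
    }
    s = []
    if good:
        s.append((0, f"Data quality is good: {_fmt(pct)}% of expected readings were "
                     f"captured over {_fmt(days)} of {_fmt(expected_days)} days."))
    else:
        s.append((0, f"Data quality is insufficient for confident interpretation: only "
                     f"{_fmt(pct)}% of expected readings over {_fmt(days)} of "
                     f"{_fmt(expected_days)} days."))
    if n_gaps:
        s.append((1, f"The sensor recorded {_fmt(n_gaps)} gap(s) totalling "
                     f"{_fmt(gap_min)} minutes; those windows are excluded from all "
                     f"event counts."))
    else:
        s.append((1, "There were no sensor gaps."))
    flags = () if good else ("insufficient_data",)
    return _finish("data_quality", facts, s, flags)


def _per_day(series: GlucoseSeries):
    dates = series.timestamps.normalize()
    return [(pd.Timestamp(d), series.values[dates == d]) for d in dates.unique()]


def analyze_hyperglycemia(
    series: GlucoseSeries,
    bands: AGPBands | None = None,
    rules: SummaryRules = DEFAULT_RULES,
) -> Finding:
    """Inter-day trends (worst days by time above range), intraday trend
    (clock window of maximal median above 180), and prolonged hyperglycemia
    (> 250 mg/dL sustained >= 120 min).  Severity labels are strictly
    threshold-gated."""
    if len(series) == 0:
        raise ValueError("analyze_hyperglycemia of an empty series")
    if bands is None:
        bands = compute_bands(series)
    tir = time_in_ranges(series)
    tar, tar250 = _round(tir.pct_above_180), _round(tir.pct_above_250)
    by_day = [
        (d, _round(100.0 * np.count_nonzero(v > rules.hyper_threshold) / len(v)),
            _round(100.0 * np.count_nonzero(v > rules.hyper_level2) / len(v)))
        for d, v in _per_day(series)
    ]
    worst = sorted((x for x in by_day if x[1] > 0), key=lambda x: (-x[1], x[0]))[:3]
    episodes = [
        e for e in detect_episodes(
            series, rules.hyper_level2, "above",
            min_duration=rules.min_duration_min, end_recovery=rules.end_recovery_min,
            censor_gap_min=rules.censor_gap_min, level2_threshold=rules.hyper_level2,
            rules=rules,
        ) if e.prolonged
    ]
    occ = bands.occupied() & ~np.isnan(bands.p50)
    window = None
    if occ.any():
        p50 = np.where(occ, bands.p50, -np.inf)
        b = int(np.argmax(p50))
        if p50[b] > rules.hyper_threshold:
            window = (int(bands.bin_starts_min[b]),
                      int(bands.bin_starts_min[b]) + bands.bin_width_min)
    # Severity gate: adjectives must be earned by the numbers.
    if tar < 1.0 and not episodes:
        severity = "none"
    elif tar <= 25.0 and tar250 <= 2.0 and not episodes:
        severity = "mild"
    elif tar <= 50.0 and tar250 <= 10.0:
        severity = "moderate"
    else:
        severity = "notable"
    n_gaps, gap_min = _gap_facts(series)
    facts = {
        "pct_above_180": tar, "pct_above_250": tar250, "severity": severity,
        "worst_days": [(d.date().isoformat(), t, t2) for d, t, t2 in worst],
        "n_prolonged_episodes": len(episodes),
        "prolonged_episodes": [
            {"start": str(e.start), "duration_min": _round(e.duration_min),
             "peak": _round(e.extremum)} for e in episodes
        ],
        "max_median_window": f"{_clock(window[0])}-{_clock(window[1])}" if window else None,
        "n_gaps": n_gaps, "gap_minutes": gap_min,
        "thresholds": {"level1": rules.hyper_threshold, "level2": rules.hyper_level2,
                       "prolonged_min": rules.prolonged_min},
    }
    s = []
    if severity == "none":
        s.append((0, f"There was no meaningful hyperglycemia: time above 180 mg/dL was "
                     f"{_fmt(tar)}% and no reading pattern exceeded 250 mg/dL."))
    else:
        s.append((0, f"Hyperglycemia burden is {severity}: {_fmt(tar)}% of readings "
                     f"above 180 mg/dL, of which {_fmt(tar250)}% were above 250 mg/dL."))
    if worst:
        days_txt = ", ".join(f"{d.date().isoformat()} ({_fmt(t)}% above 180)" for d, t, _ in worst)
        s.append((1, f"The highest-exposure days were {days_txt}."))
    if window is not None:
        s.append((2, f"Across days, the median glucose was highest and above range "
                     f"between {_clock(window[0])} and {_clock(window[1])}."))
    if episodes:
        e0 = episodes[0]
        s.append((1, f"Prolonged hyperglycemia above 250 mg/dL occurred "
                     f"{_fmt(len(episodes))} time(s), the first starting "
                     f"{e0.start} and lasting {_fmt(e0.duration_min)} minutes "
                     f"(peak {_fmt(e0.extremum)} mg/dL)."))
    else:
        s.append((3, _absence_sentence("prolonged hyperglycemia above 250 mg/dL",
                                       n_gaps, gap_min)))
    flags = []
    if episodes:
        flags.append("prolonged_hyper")
    if severity in ("moderate", "notable"):
        flags.append("hyper_burden")
    return _finish("hyperglycemia", facts, s, flags)


def analyze_hypoglycemia(
    series: GlucoseSeries,
    rules: SummaryRules = DEFAULT_RULES,
) -> Finding:
    """Hypoglycemic episodes (< 70 mg/dL, >= 15 min), with level-2 (< 54),
    prolonged (>= 120 min) and nocturnal (any overlap with 00:00-06:00)
    flags.  Nocturnal and level-2 events always surface in the narrative;
    overnight readings in [70, 80) are reported as near-misses."""
    if len(series) == 0:
        raise ValueError("analyze_hypoglycemia of an empty series")
    episodes = detect_episodes(
        series, rules.hypo_threshold, "below",
        min_duration=rules.min_duration_min, end_recovery=rules.end_recovery_min,
        censor_gap_min=rules.censor_gap_min, level2_threshold=rules.hypo_level2,
        rules=rules,
    )
    tir = time_in_ranges(series)
    tbr, tb54 = _round(tir.pct_below_70), _round(tir.pct_below_54)
    nocturnal = [e for e in episodes if e.nocturnal]
    level2 = [e for e in episodes if e.level == 2]
    prolonged = [e for e in episodes if e.prolonged]
    clock = series.timestamps.hour * 60 + series.timestamps.minute
    overnight = (np.asarray(clock) >= rules.nocturnal_start_min) & (
        np.asarray(clock) < rules.nocturnal_end_min)
    near = overnight & (series.values >= rules.near_miss_low) & (
        series.values < rules.near_miss_high)
    near_count = int(np.count_nonzero(near))
    near_days = int(len(np.unique(series.timestamps.normalize().asi8[near])))
    n_gaps, gap_min = _gap_facts(series)
    facts = {
        "n_episodes": len(episodes), "n_nocturnal": len(nocturnal),
        "n_level2": len(level2), "n_prolonged": len(prolonged),
        "pct_below_70": tbr, "pct_below_54": tb54,
        "lowest": _round(min((e.extremum for e in episodes), default=np.nan))
        if episodes else None,
        "episodes": [
            {"start": str(e.start), "duration_min": _round(e.duration_min),
             "nadir": _round(e.extremum), "level": e.level,
             "nocturnal": e.nocturnal, "prolonged": e.prolonged} for e in episodes
        ],
        "near_miss_count": near_count, "near_miss_days": near_days,
        "n_gaps": n_gaps, "gap_minutes": gap_min,
        "nocturnal_window": f"{_clock(rules.nocturnal_start_min)}-{_clock(rules.nocturnal_end_min)}",
        "thresholds": {"level1": rules.hypo_threshold, "level2": rules.hypo_level2,
                       "prolonged_min": rules.prolonged_min,
                       "min_duration_min": rules.min_duration_min,
                       "near_miss_low": rules.near_miss_low,
                       "near_miss_high": rules.near_miss_high},
    }
    s = []
    if nocturnal:  # always surfaces, whatever the counts
        e0 = nocturnal[0]
        s.append((0, f"Nocturnal hypoglycemia occurred: {_fmt(len(nocturnal))} "
                     f"episode(s) overlapped the 00:00-06:00 window, the first "
                     f"starting {e0.start} with a nadir of {_fmt(e0.extremum)} mg/dL."))
    if level2:  # always surfaces
        s.append((0, f"Level 2 hypoglycemia (below 54 mg/dL) occurred in "
                     f"{_fmt(len(level2))} episode(s)."))
    if episodes:
        s.append((1, f"Overall there were {_fmt(len(episodes))} hypoglycemic "
                     f"episode(s) below 70 mg/dL; time below 70 mg/dL was "
                     f"{_fmt(tbr)}% and time below 54 mg/dL was {_fmt(tb54)}%."))
    else:
        s.append((1, _absence_sentence("hypoglycemia below 70 mg/dL sustained 15 minutes",
                                       n_gaps, gap_min)))
    if prolonged:
        s.append((1, f"{_fmt(len(prolonged))} episode(s) were prolonged "
                     f"(at least 120 minutes below range)."))
    if near_count:
        s.append((2, f"Overnight glucose approached the hypoglycemic threshold "
                     f"(70-80 mg/dL) in {_fmt(near_count)} reading(s) across "
                     f"{_fmt(near_days)} night(s)."))
    if len(s) < 2:
        s.append((3, f"Time below 70 mg/dL was {_fmt(tbr)}% of readings."))
    flags = []
    if level2:
        flags.append("level2_hypo")
    if nocturnal:
        flags.append("nocturnal_hypo")
    if prolonged:
        flags.append("prolonged_hypo")
    if episodes:
        flags.append("hypo")
    if near_count:
        flags.append("nocturnal_near_miss")
    return _finish("hypoglycemia", facts, s, flags)


def analyze_variability(
    series: GlucoseSeries,
    bands: AGPBands | None = None,
    rules: SummaryRules = DEFAULT_RULES,
) -> Finding:
    """Overall and per-day coefficient of variation, days above the 36% CV
    target, and the clock window of maximal interquartile range.  The word
    "stable" is never used when the GMI is in the high range, however low
    the CV: uniform hyperglycemia is not stability."""
    if len(series) == 0:
        raise ValueError("analyze_variability of an empty series")
    if bands is None:
        bands = compute_bands(series)
    overall_cv = _round(cv_metric(series))
    g = _round(gmi_of_mean(mean_glucose(series)))
    day_cv = []
    for d, v in _per_day(series):
        m = float(np.mean(v))
        if m > 0:
            day_cv.append((d, _round(100.0 * float(np.std(v)) / m)))
    high_days = [(d, c) for d, c in day_cv if c > rules.high_cv_pct]
    prof = iqr_profile(bands)
    w0, w1 = prof.max_window
    facts = {
        "cv": overall_cv, "gmi": g,
        "n_high_cv_days": len(high_days),
        "high_cv_days": [(d.date().isoformat(), c) for d, c in high_days],
        "max_iqr": _round(prof.max_iqr),
        "max_iqr_window": f"{_clock(w0)}-{_clock(w1)}",
        "thresholds": {"high_cv_pct": rules.high_cv_pct},
    }
    s = []
    if overall_cv > rules.high_cv_pct:
        s.append((0, f"Glycemic variability is high: overall CV {_fmt(overall_cv)}%, "
                     f"above the {_fmt(rules.high_cv_pct)}% target."))
    elif g >= rules.gmi_high_pct:
        # Low CV with a high GMI is uniform hyperglycemia, not stability.
        s.append((0, f"Overall CV is {_fmt(overall_cv)}%, within the "
                     f"{_fmt(rules.high_cv_pct)}% target, but glucose was persistently "
                     f"elevated (GMI {_fmt(g)}%), so the low variability reflects "
                     f"consistent hyperglycemia rather than good control."))
    else:
        s.append((0, f"Glycemic variability is within target and control is stable: "
                     f"overall CV {_fmt(overall_cv)}% against the "
                     f"{_fmt(rules.high_cv_pct)}% target."))
    if high_days:
        days_txt = ", ".join(f"{d.date().isoformat()} (CV {_fmt(c)}%)" for d, c in high_days[:3])
        s.append((1, f"{_fmt(len(high_days))} day(s) exceeded the CV target, "
                     f"including {days_txt}."))
    else:
        s.append((2, f"No single day exceeded the {_fmt(rules.high_cv_pct)}% CV target."))
    s.append((1, f"The interquartile range is widest between {_clock(w0)} and "
                 f"{_clock(w1)} ({_fmt(prof.max_iqr)} mg/dL), the first window to "
                 f"review for inconsistent routines."))
    flags = []
    if overall_cv > rules.high_cv_pct:
        flags.append("high_cv")
    if high_days:
        flags.append("high_cv_days")
    return _finish("variability", facts, s, flags)


def main_clinical_concern(
    report: MetricReport,
    findings: dict,
    rules: SummaryRules = DEFAULT_RULES,
) -> Finding:
    """First matching rule wins: (1) level-2 hypoglycemia or time below
    70 >= 4% -> hypoglycemia; (2) any nocturnal episode -> nocturnal
    hypoglycemia; (3) TIR < 70% or GMI >= 8% -> hyperglycemia burden;
    (4) CV > 36% -> variability; (5) otherwise the case meets targets.
    The narrative always restates GMI and TIR."""
    missing = [t for t in ("data_quality", "hyperglycemia", "hypoglycemia", "variability")
               if t not in findings]
    if missing:
        raise ValueError(f"main_clinical_concern requires findings for {missing}")
    hypo = findings["hypoglycemia"].facts
    var = findings["variability"].facts
    g, tir = _round(report.gmi), _round(report.pct_70_180)
    tbr, cv_val = _round(report.pct_below_70), _round(report.cv)
    if hypo["n_level2"] > 0 or tbr >= rules.tbr_concern_pct:
        concern = "hypoglycemia"
        lead = (f"The primary clinical concern is hypoglycemia: "
                f"{_fmt(hypo['n_level2'])} level 2 episode(s) and {_fmt(tbr)}% of "
                f"time below 70 mg/dL.")
    elif hypo["n_nocturnal"] > 0:
        concern = "nocturnal_hypoglycemia"
        lead = (f"The primary clinical concern is nocturnal hypoglycemia: "
                f"{_fmt(hypo['n_nocturnal'])} episode(s) overlapped the "
                f"00:00-06:00 window.")
    elif tir < rules.tir_target_pct or g >= rules.gmi_high_pct:
        concern = "hyperglycemia"
        lead = (f"The primary clinical concern is hyperglycemia burden: time in "
                f"range is {_fmt(tir)}% (target at least "
                f"{_fmt(rules.tir_target_pct)}%) with "
                f"{_fmt(report.pct_above_180)}% of time above 180 mg/dL.")
    elif cv_val > rules.high_cv_pct:
        concern = "variability"
        lead = (f"The primary clinical concern is glycemic variability: CV "
                f"{_fmt(cv_val)}% exceeds the {_fmt(rules.high_cv_pct)}% target.")
    else:
        concern = "meets_targets"
        lead = ("There is no primary clinical concern: the case meets consensus "
                "targets, so the current regimen should be reinforced.")
    facts = {
        "concern": concern, "gmi": g, "tir": tir, "tbr": tbr, "cv": cv_val,
        "pct_above_180": _round(report.pct_above_180),
        "n_level2_hypo": hypo["n_level2"], "n_nocturnal_hypo": hypo["n_nocturnal"],
        "n_hypo_episodes": hypo["n_episodes"], "days_active": report.days_active,
        "nocturnal_window": f"{_clock(rules.nocturnal_start_min)}-{_clock(rules.nocturnal_end_min)}",
        "thresholds": {"tir_target_pct": rules.tir_target_pct,
                       "gmi_high_pct": rules.gmi_high_pct,
                       "high_cv_pct": rules.high_cv_pct,
                       "tbr_concern_pct": rules.tbr_concern_pct,
                       "range_low": 70.0, "range_high": 180.0},
    }
    s = [(0, lead),
         (0, f"Over {_fmt(report.days_active)} days the GMI was {_fmt(g)}% and time "
             f"in range (70-180 mg/dL) was {_fmt(tir)}%.")]
    if concern in ("hypoglycemia", "nocturnal_hypoglycemia") and hypo["n_episodes"]:
        s.append((1, f"Review the {_fmt(hypo['n_episodes'])} hypoglycemic episode(s) "
                     f"before addressing anything else."))
    if concern == "hyperglycemia" and var["cv"] <= rules.high_cv_pct:
        s.append((2, f"Variability is acceptable (CV {_fmt(var['cv'])}%), so the "
                     f"elevation is consistent rather than erratic."))
    flags = () if concern == "meets_targets" else (concern,)
    return _finish("main_concern", facts, s, flags)


def summarize_case(
    series: GlucoseSeries,
    report: MetricReport,
    bands: AGPBands | None = None,
    expected_days: int = 14,
    rules: SummaryRules = DEFAULT_RULES,
) -> dict:
    """Run all five summarization tasks for one case."""
    if bands is None:
        bands = compute_bands(series)
    findings = {
        "data_quality": assess_data_quality(series, expected_days, rules),
        "hyperglycemia": analyze_hyperglycemia(series, bands, rules),
        "hypoglycemia": analyze_hypoglycemia(series, rules),
        "variability": analyze_variability(series, bands, rules),
    }
    findings["main_concern"] = main_clinical_concern(report, findings, rules)
    return findings
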