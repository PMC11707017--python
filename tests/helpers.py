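"""Shared fixtures helpers and independent oracles used across the suite.

The oracles here are deliberately naive (explicit loops, run-length
encodings, literal formula transcriptions) and never share code with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cgmkit.io import GlucoseSeries

START = pd.Timestamp("2024-03-01 00:00:00")


def make_series(values, start=START, interval=5, times=None) -> GlucoseSeries:
    vals = np.asarray(values, dtype=float)
    if times is None:
        times = start + pd.to_timedelta(np.arange(len(vals)) * interval, unit="min")
    return GlucoseSeries(pd.DatetimeIndex(times), vals, nominal_interval=interval)


def brute_force_metrics(values) -> dict:
    """Naive loop over readings: the independent oracle for the range
    percentages, mean and CV."""
    n = len(values)
    c250 = c180 = c180_250 = cin = c70 = c54 = 0
    total = 0.0
    for v in values:
        total += v
        if v > 250:
            c250 += 1
        if v > 180:
            c180 += 1
        if 180 < v <= 250:
            c180_250 += 1
        if 70 <= v <= 180:
            cin += 1
        if v < 70:
            c70 += 1
        if v < 54:
            c54 += 1
    mean = total / n
    var = sum((v - mean) ** 2 for v in values) / n
    return {
        "mean": mean,
        "cv": 100.0 * var**0.5 / mean,
        "pct_above_250": 100.0 * c250 / n,
        "pct_above_180_cum": 100.0 * c180 / n,
        "pct_above_180_banded": 100.0 * c180_250 / n,
        "pct_70_180": 100.0 * cin / n,
        "pct_below_70": 100.0 * c70 / n,
        "pct_below_54": 100.0 * c54 / n,
    }


def episodes_oracle(
    minutes, values, interval, threshold, direction,
    min_duration=15.0, end_recovery=15.0, censor_gap=30.0,
):
    """Run-length-encoding episode finder: split at gaps, encode runs of
    out/in readings, then merge runs.  Returns (start_min, last_out_min,
    extremum) triples."""
    out_of = (lambda v: v < threshold) if direction == "below" else (lambda v: v > threshold)
    segments, cur = [], [0]
    for i in range(1, len(minutes)):
        if minutes[i] - minutes[i - 1] > censor_gap:
            segments.append(cur)
            cur = []
        cur.append(i)
    segments.append(cur)

    episodes = []
    for seg in segments:
        runs = []  # (is_out, [indices])
        for i in seg:
            o = out_of(values[i])
            if runs and runs[-1][0] == o:
                runs[-1][1].append(i)
            else:
                runs.append((o, [i]))
        span = lambda idxs: (minutes[idxs[-1]] - minutes[idxs[0]]) + interval
        k = 0
        while k < len(runs):
            o, idxs = runs[k]
            if not o or span(idxs) < min_duration:
                k += 1
                continue
            start = minutes[idxs[0]]
            last_out = minutes[idxs[-1]]
            ext_fn = min if direction == "below" else max
            ext = ext_fn(values[i] for i in idxs)
            j = k + 1
            while j < len(runs):
                o2, idxs2 = runs[j]
                if o2:
                    last_out = minutes[idxs2[-1]]
                    ext = ext_fn([ext] + [values[i] for i in idxs2])
                elif span(idxs2) >= end_recovery:
                    break
                j += 1
            episodes.append((start, last_out, ext))
            k = j
    return episodes


def ac1_literal(a, b) -> float:
    """Literal transcription of the two-rater binary AC1 formula."""
    n = len(a)
    pa = sum(1 for x, y in zip(a, b) if x == y) / n
    pi_hat = (sum(map(bool, a)) / n + sum(map(bool, b)) / n) / 2.0
    pe = 2.0 * pi_hat * (1.0 - pi_hat)
    return (pa - pe) / (1.0 - pe)


def random_episode_fixture(rng, n=120, interval=5):
    """A jagged series around the clinical thresholds, with dropped
    readings and occasional long gaps, for episode-detector fuzzing."""
    minutes = np.arange(n) * interval
    keep = rng.random(n) > 0.08
    keep[0] = True
    minutes = minutes[keep]
    for _ in range(rng.integers(0, 3)):  # insert a long gap
        if len(minutes) > 20:
            cut = rng.integers(5, len(minutes) - 5)
            minutes = np.concatenate([minutes[:cut], minutes[cut:] + 45])
    # random walk spanning hypo and hyper territory
    vals = np.clip(np.cumsum(rng.normal(0, 25, len(minutes))) + 120, 39, 401)
    times = START + pd.to_timedelta(minutes, unit="min")
    return GlucoseSeries(pd.DatetimeIndex(times), vals, nominal_interval=interval)
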