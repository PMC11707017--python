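"""Standard ambulatory-glucose-profile summary metrics.

Implements the ten descriptive metrics printed at the top of an AGP report:
days of sensor wear, % of data captured, mean glucose, Glucose Management
Indicator (GMI), coefficient of variation (CV), and the five time-in-range
percentages (time above 250, above 180, in 70-180, below 70, below 54 mg/dL).

Two time-above-range conventions are supported and always recorded:

* ``cumulative`` (the default, and the clinical ground truth): time above
  180 mg/dL counts every reading with g > 180.
* ``banded``: time above 180 reports only the level-1 band
  (180 mg/dL < g <= 250 mg/dL, i.e. 181-250 on integer readings), so that
  banded level-1 + time above 250 equals the cumulative figure exactly.
  The banded reading of "level 1" is a common mis-application of the
  cumulative definition, and exposing it lets an analysis diagnose it.

Every percentage is a reading-count fraction of the observed readings; gaps
are excluded from the denominator rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SENSOR_CEILING, SENSOR_FLOOR, GlucoseSeries

CONVENTIONS = ("cumulative", "banded")


@dataclass(frozen=True)
class GMIConstants:
    """GMI is a linear map of mean CGM glucose onto the HbA1c % scale:
    gmi = intercept + slope * mean_glucose."""

    intercept: float = 3.31
    slope: float = 0.02392  # % per (mg/dL)


GMI_DEFAULT = GMIConstants()


@dataclass(frozen=True)
class MetricReport:
    """The ten AGP summary metrics plus the time-above-range convention used."""

    days_active: int
    pct_captured: float
    mean_glucose: float
    gmi: float
    cv: float
    pct_above_250: float
    pct_above_180: float
    pct_70_180: float
    pct_below_70: float
    pct_below_54: float
    tar_convention: str = "cumulative"

    def to_dict(self) -> dict:
        return {
            "days_active": self.days_active,
            "pct_captured": self.pct_captured,
            "mean_glucose": self.mean_glucose,
            "gmi": self.gmi,
            "cv": self.cv,
            "pct_above_250": self.pct_above_250,
            "pct_above_180": self.pct_above_180,
            "pct_70_180": self.pct_70_180,
            "pct_below_70": self.pct_below_70,
            "pct_below_54": self.pct_below_54,
            "tar_convention": self.tar_convention,
        }


def days_active(series: GlucoseSeries) -> int:
    """Number of distinct calendar dates with at least one reading."""
    if len(series) == 0:
        return 0
    return int(len(np.unique(series.timestamps.normalize().asi8)))


def percent_captured(series: GlucoseSeries, expected_days: int, interval: int | None = None) -> float:
    """100 x observed readings / (expected_days x 1440/interval)."""
    if expected_days < 1:
        raise ValueError("expected_days must be >= 1")
    if interval is None:
        interval = series.nominal_interval
    if 1440 % interval:
        raise ValueError(f"interval {interval} min does not divide 1440")
    expected = expected_days * (1440 // interval)
    return 100.0 * len(series) / expected


def mean_glucose(series: GlucoseSeries) -> float:
    """Unweighted arithmetic mean of the readings, mg/dL."""
    if len(series) == 0:
        raise ValueError("mean_glucose of an empty series")
    return float(np.mean(series.values))


def gmi(mean: float, constants: GMIConstants = GMI_DEFAULT) -> float:
    """Glucose Management Indicator (%) from mean glucose (mg/dL)."""
    if not (SENSOR_FLOOR <= mean <= SENSOR_CEILING):
        raise ValueError(f"mean glucose {mean} outside [{SENSOR_FLOOR}, {SENSOR_CEILING}]")
    return constants.intercept + constants.slope * mean


def mean_for_gmi(target_gmi: float, constants: GMIConstants = GMI_DEFAULT) -> float:
    """Invert the GMI line: the mean glucose (mg/dL) that realizes a GMI."""
    return (target_gmi - constants.intercept) / constants.slope


def cv(series: GlucoseSeries) -> float:
    """Coefficient of variation, %: 100 x population SD / mean.

    The series is treated as the entire observation window, so the
    population (ddof=0) standard deviation is used.
    """
    if len(series) == 0:
        raise ValueError("cv of an empty series")
    m = float(np.mean(series.values))
    if m <= 0:
        raise ValueError("cv undefined for non-positive mean")
    return 100.0 * float(np.std(series.values)) / m


@dataclass(frozen=True)
class TimeInRanges:
    pct_above_250: float
    pct_above_180: float
    pct_70_180: float
    pct_below_70: float
    pct_below_54: float
    convention: str


def time_in_ranges(series: GlucoseSeries, convention: str = "cumulative") -> TimeInRanges:
    """The five time-in-range percentages as reading-count fractions.

    Boundaries: above 250 means g > 250; cumulative above 180 means
    g > 180; banded level 1 means 180 < g <= 250; in range means
    70 <= g <= 180; below 70 means g < 70; below 54 means g < 54.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    g = series.values
    n = len(g)
    if n == 0:
        raise ValueError("time_in_ranges of an empty series")
    pct = lambda mask: 100.0 * int(np.count_nonzero(mask)) / n
    above_250 = pct(g > 250)
    above_180 = pct(g > 180) if convention == "cumulative" else pct((g > 180) & (g <= 250))
    return TimeInRanges(
        pct_above_250=above_250,
        pct_above_180=above_180,
        pct_70_180=pct((g >= 70) & (g <= 180)),
        pct_below_70=pct(g < 70),
        pct_below_54=pct(g < 54),
        convention=convention,
    )


def metric_report(
    series: GlucoseSeries,
    expected_days: int = 14,
    convention: str = "cumulative",
    constants: GMIConstants = GMI_DEFAULT,
) -> MetricReport:
    """Assemble the full ten-metric report for one case."""
    if len(series) == 0:
        raise ValueError("metric_report of an empty series")
    m = mean_glucose(series)
    tir = time_in_ranges(series, convention=convention)
    return MetricReport(
        days_active=days_active(series),
        pct_captured=percent_captured(series, expected_days),
        mean_glucose=m,
        gmi=gmi(m, constants),
        cv=cv(series),
        pct_above_250=tir.pct_above_250,
        pct_above_180=tir.pct_above_180,
        pct_70_180=tir.pct_70_180,
        pct_below_70=tir.pct_below_70,
        pct_below_54=tir.pct_below_54,
        tar_convention=convention,
    )
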