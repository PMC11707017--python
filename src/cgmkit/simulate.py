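r"""Synthetic type-1-diabetes CGM case generation.

Generates multi-day interstitial glucose traces with controllable glycemic
quality, standing in for a full physiological patient simulator.  The
dynamics are a Bergman minimal model driven by meal and insulin inputs:

    dG/dt = -p1 (G - Gb) - X G + Ra(t)          plasma glucose, mg/dL
    dX/dt = -p2 X + p3 (I(t) - Ib)              remote insulin action, 1/min

with meal glucose appearance Ra from a two-compartment absorption cascade
(rate ka for both compartments, so a carb impulse of c grams produces
Ra(t) = f_carb c ka^2 t e^{-ka t}), and plasma insulin

    I(t) = dose_scale * Ib  +  ki * D(t),    dD/dt = -ki D + bolus impulses,

i.e. first-order absorption of basal + bolus delivery, with every unit of
delivery multiplied by the single calibration knob ``dose_scale``.  With no
meals and dose_scale = 1 the state (Gb, 0) is an exact equilibrium; raising
dose_scale lowers glucose everywhere, so realized mean glucose is monotone
in the knob and one-dimensional bisection can pin the realized Glucose
Management Indicator (GMI) to any achievable target.

Day-to-day variation in insulin requirements — the dominant source of
glycemic variability in T1D — is modeled as a per-day lognormal multiplier
on all insulin delivery (sigma ``day_sens_sd``), so some days run high and
some run low around the calibrated mean.

The sensor model applies a first-order interstitial lag (time constant
``tau_lag``), samples every ``interval_min`` minutes, adds multiplicative
AR(1) Gaussian noise, quantizes to 1 mg/dL, and clamps to the reporting
range [39, 401] mg/dL.  Missing-data gaps are then cut out as contiguous
blocks.  Randomness is split into named substreams per case
(0 = meal realization, 1 = sensor noise, 2 = gaps, 3 = day-to-day insulin
sensitivity), each seeded as ``default_rng([case_seed, stream])``, so
calibration — which re-simulates the fixed meal/sensitivity realization
with no randomness — and future features can never silently shift each
other's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import GlucoseSeries, clamp_values
from .metrics import GMI_DEFAULT, GMIConstants, gmi as gmi_of_mean, mean_for_gmi

__all__ = [
    "PatientParams", "SensorParams", "MealEvent", "BolusPolicy", "GapSpec",
    "CaseConfig", "Trace", "CalibrationError", "simulate_patient",
    "sample_sensor", "inject_missingness", "calibrate_to_gmi",
    "generate_case", "generate_suite", "DEFAULT_BASE_SEED",
]

#: Base seed of the default generated suite.
DEFAULT_BASE_SEED = 7

_MEAL_STREAM, _NOISE_STREAM, _GAP_STREAM, _DAYSENS_STREAM = 0, 1, 2, 3
_KERNEL_MIN = 720  # impulse-response support, minutes (decay < 1e-7 beyond)

DOSE_SCALE_MIN, DOSE_SCALE_MAX = 0.1, 10.0


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PatientParams:
    """Minimal-model parameters for a T1D adult.

    Defaults are drawn from the usual minimal-model ranges, with insulin
    sensitivity (p3) set high enough that dose_scale in [0.1, 10] sweeps
    realized GMI well past the 6-9 % band of interest.
    """

    Gb: float = 110.0          # basal plasma glucose, mg/dL
    p1: float = 0.02           # glucose effectiveness, 1/min
    p2: float = 0.028          # insulin action decay, 1/min
    p3: float = 2.5e-5         # insulin sensitivity gain, 1/min per (uU/mL)
    Ib: float = 15.0           # basal plasma insulin, uU/mL
    ka: float = 0.035          # meal absorption rate, 1/min
    f_carb: float = 8.0        # carb-to-glucose appearance scale, mg/dL per g
    ki: float = 0.025          # insulin absorption rate, 1/min
    bolus_gain: float = 1500.0 # plasma insulin exposure per unit, uU/mL*min per U
    day_sens_sd: float = 0.2   # lognormal sigma of the per-day insulin multiplier
    dose_scale: float = 1.0    # multiplier on all insulin delivery

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "ka", "ki"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be > 0")
        if not (70.0 <= self.Gb <= 300.0):
            raise ValueError("Gb must lie in [70, 300] mg/dL")
        if not (DOSE_SCALE_MIN <= self.dose_scale <= DOSE_SCALE_MAX):
            raise ValueError(f"dose_scale must lie in [{DOSE_SCALE_MIN}, {DOSE_SCALE_MAX}]")


@dataclass(frozen=True)
class SensorParams:
    """Interstitial CGM sensor error model."""

    tau_lag: float = 10.0   # interstitial lag time constant, minutes
    noise_cv: float = 0.05  # multiplicative noise coefficient of variation
    ar_phi: float = 0.7     # AR(1) autocorrelation of the noise
    quantize: float = 1.0   # reporting resolution, mg/dL (0 disables)

    def __post_init__(self) -> None:
        if self.tau_lag < 0:
            raise ValueError("tau_lag must be >= 0")
        if not (0.0 <= self.noise_cv <= 0.2):
            raise ValueError("noise_cv must lie in [0, 0.2]")
        if not (0.0 <= self.ar_phi < 1.0):
            raise ValueError("ar_phi must lie in [0, 1)")


@dataclass(frozen=True)
class MealEvent:
    """One scheduled daily meal: nominal clock time and carbs, with the
    per-day uniform jitter applied to each."""

    clock_min: int          # minutes after midnight
    carbs_g: float
    carb_jitter_g: float = 0.0
    time_jitter_min: float = 0.0


@dataclass(frozen=True)
class BolusPolicy:
    """Carbs-to-insulin dosing: units = carbs / icr, delivered at the meal
    time plus ``timing_offset_min``."""

    icr: float = 10.0            # grams of carbohydrate per unit
    timing_offset_min: float = 0.0


@dataclass(frozen=True)
class GapSpec:
    """Per-day missing-data mechanism: with probability ``prob_per_day`` one
    contiguous gap of uniform length in [min_minutes, max_minutes]."""

    prob_per_day: float = 0.3
    min_minutes: float = 30.0
    max_minutes: float = 120.0


def _default_meals() -> tuple[MealEvent, ...]:
    return (
        MealEvent(clock_min=450, carbs_g=60.0, carb_jitter_g=15.0, time_jitter_min=25.0),
        MealEvent(clock_min=750, carbs_g=80.0, carb_jitter_g=20.0, time_jitter_min=35.0),
        MealEvent(clock_min=1110, carbs_g=95.0, carb_jitter_g=20.0, time_jitter_min=35.0),
    )


@dataclass(frozen=True)
class CaseConfig:
    """Per-case generation recipe.  A fixed seed makes generation fully
    reproducible, byte-for-byte."""

    case_id: str = "case"
    duration_days: int = 14
    interval_min: int = 5
    target_gmi: float = 7.0
    meal_schedule: tuple[MealEvent, ...] = field(default_factory=_default_meals)
    bolus_policy: BolusPolicy = field(default_factory=BolusPolicy)
    missingness: tuple[GapSpec, ...] = (GapSpec(),)
    seed: int = 0
    start: pd.Timestamp = pd.Timestamp("2024-03-01 00:00:00")

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if not (5.0 <= self.target_gmi <= 12.0):
            raise ValueError("target_gmi must lie in [5.0, 12.0] %")
        if self.interval_min <= 0 or 1440 % self.interval_min:
            raise ValueError("interval_min must divide 1440")

    @property
    def n_minutes(self) -> int:
        return self.duration_days * 1440


class Trace(NamedTuple):
    """Dense noise-free glucose trace at 1-minute resolution."""

    start: pd.Timestamp
    values: np.ndarray  # mg/dL, one per minute


class _MealRealization(NamedTuple):
    meal_minutes: np.ndarray   # minute index of each carb impulse
    meal_carbs: np.ndarray     # grams
    bolus_minutes: np.ndarray  # minute index of each bolus impulse
    bolus_units: np.ndarray    # U


def _realize_meals(config: CaseConfig, rng: np.random.Generator) -> _MealRealization:
    """Draw the per-day meal times/carbs and derive boluses.  Draw order is
    fixed: days outer, meals inner, time jitter before carb jitter."""
    mt, mc, bt, bu = [], [], [], []
    policy = config.bolus_policy
    for day in range(config.duration_days):
        day0 = day * 1440
        for meal in config.meal_schedule:
            t_jit = rng.uniform(-meal.time_jitter_min, meal.time_jitter_min) if meal.time_jitter_min else 0.0
            c_jit = rng.uniform(-meal.carb_jitter_g, meal.carb_jitter_g) if meal.carb_jitter_g else 0.0
            minute = int(round(day0 + meal.clock_min + t_jit))
            carbs = max(0.0, meal.carbs_g + c_jit)
            if not (0 <= minute < config.n_minutes) or carbs <= 0:
                continue
            mt.append(minute)
            mc.append(carbs)
            b_minute = int(round(minute + policy.timing_offset_min))
            units = carbs / policy.icr if policy.icr > 0 else 0.0
            if 0 <= b_minute < config.n_minutes and units > 0:
                bt.append(b_minute)
                bu.append(units)
    return _MealRealization(
        np.asarray(mt, dtype=int), np.asarray(mc, dtype=float),
        np.asarray(bt, dtype=int), np.asarray(bu, dtype=float),
    )


def _impulse_sum(n: int, times: np.ndarray, amplitudes: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum of shifted scaled copies of ``kernel`` starting at each impulse."""
    out = np.zeros(n)
    for t, a in zip(times, amplitudes):
        w = min(len(kernel), n - t)
        if w > 0:
            out[t:t + w] += a * kernel[:w]
    return out


def simulate_patient(
    params: PatientParams,
    config: CaseConfig,
    _meals: _MealRealization | None = None,
) -> Trace:
    """Integrate the minimal-model ODEs over the case duration at 1-minute
    resolution (classical Runge-Kutta on the glucose state, exact discrete
    solutions for the linear meal / insulin / insulin-action subsystems)."""
    n = config.n_minutes
    if _meals is None:
        _meals = _realize_meals(config, np.random.default_rng([config.seed, _MEAL_STREAM]))
    s = params.dose_scale

    # Per-day insulin-delivery multiplier (day-to-day insulin sensitivity).
    if params.day_sens_sd > 0:
        rng_day = np.random.default_rng([config.seed, _DAYSENS_STREAM])
        day_factor = np.exp(rng_day.normal(0.0, params.day_sens_sd, config.duration_days))
    else:
        day_factor = np.ones(config.duration_days)

    t_k = np.arange(_KERNEL_MIN, dtype=float)
    ra_kernel = params.f_carb * params.ka**2 * t_k * np.exp(-params.ka * t_k)
    Ra = _impulse_sum(n, _meals.meal_minutes, _meals.meal_carbs, ra_kernel)

    ins_kernel = params.ki * np.exp(-params.ki * t_k)  # plasma insulin per unit depot
    depot0 = (
        s * _meals.bolus_units * params.bolus_gain * day_factor[_meals.bolus_minutes // 1440]
        if len(_meals.bolus_minutes) else np.empty(0)
    )
    I_bolus = _impulse_sum(n, _meals.bolus_minutes, depot0, ins_kernel)

    # Plasma insulin deviation from basal and the first-order response of
    # remote insulin action X (trapezoid discretization of the exact
    # exponential update, second-order accurate for smooth insulin decay).
    I_tonic = s * params.Ib * np.repeat(day_factor, 1440)[:n]
    dev = I_tonic + I_bolus - params.Ib
    a2 = math.exp(-params.p2)
    c = (1.0 - a2) * params.p3 / params.p2
    x0 = (params.p3 / params.p2) * dev[0]
    X = lfilter([c / 2, c / 2], [1.0, -a2], dev, zi=[x0 - (c / 2) * dev[0]])[0]
    eff_min = params.p1 + float(X.min())
    if eff_min <= 1e-4:
        raise CalibrationError(
            f"unstable parameterization: p1 + min X = {eff_min:.2e} <= 0 at dose_scale {s}"
        )

    # Glucose state: dG/dt = -(p1 + X) G + (p1 Gb + Ra).  With X and Ra
    # frozen at their midpoint over each 1-minute step this is linear, so an
    # exponential-integrator update is exact for the frozen inputs,
    # unconditionally stable, and keeps G positive (the decay rate
    # p1 + X >= p1 - (p3/p2) Ib stays positive because I(t) >= 0).
    exp = math.exp
    p1, Gb = params.p1, params.Gb
    G = p1 * Gb / (p1 + x0)
    out = np.empty(n)
    Xl, Ral = X.tolist(), Ra.tolist()
    for t in range(n):
        out[t] = G
        if t == n - 1:
            break
        lam = p1 + 0.5 * (Xl[t] + Xl[t + 1])
        b = p1 * Gb + 0.5 * (Ral[t] + Ral[t + 1])
        e = exp(-lam)
        G = G * e + b * (1.0 - e) / lam
    if not np.all(np.isfinite(out)) or out.min() <= 0:
        raise CalibrationError("simulation produced a non-finite or non-positive trace")
    return Trace(start=config.start, values=out)


def sample_sensor(
    trace: Trace,
    sensor: SensorParams,
    config: CaseConfig,
    rng: np.random.Generator | None = None,
) -> GlucoseSeries:
    """Apply interstitial lag, sample on the grid, add AR(1) multiplicative
    noise, quantize, and clamp to the sensor range."""
    g = np.asarray(trace.values, dtype=float)
    if sensor.tau_lag > 1e-9:
        alpha = 1.0 - math.exp(-1.0 / sensor.tau_lag)
        g, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], g, zi=[(1.0 - alpha) * g[0]])
    idx = np.arange(0, len(g), config.interval_min)
    sampled = g[idx]
    if sensor.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng([config.seed, _NOISE_STREAM])
        z = rng.standard_normal(len(idx))
        innov = z * (sensor.noise_cv * math.sqrt(1.0 - sensor.ar_phi**2))
        innov[0] = z[0] * sensor.noise_cv  # stationary start
        e = lfilter([1.0], [1.0, -sensor.ar_phi], innov)
        sampled = sampled * (1.0 + e)
    if sensor.quantize > 0:
        sampled = np.round(sampled / sensor.quantize) * sensor.quantize
    sampled, _ = clamp_values(sampled)
    times = trace.start + pd.to_timedelta(idx, unit="min")
    return GlucoseSeries(pd.DatetimeIndex(times), sampled, nominal_interval=config.interval_min)


def inject_missingness(
    series: GlucoseSeries,
    config: CaseConfig,
    rng: np.random.Generator | None = None,
) -> GlucoseSeries:
    """Remove contiguous blocks of readings per the case's gap spec.
    Deterministic given the seed; never adds readings."""
    if len(series) == 0 or not config.missingness:
        return series
    if rng is None:
        rng = np.random.default_rng([config.seed, _GAP_STREAM])
    day_zero = series.timestamps[0].normalize()
    minutes = (series.timestamps.asi8 - day_zero.value) / 60e9
    keep = np.ones(len(series), dtype=bool)
    for day in range(config.duration_days):
        for spec in config.missingness:
            if rng.random() >= spec.prob_per_day:
                continue
            length = rng.uniform(spec.min_minutes, spec.max_minutes)
            start = day * 1440 + rng.uniform(0.0, max(0.0, 1440.0 - length))
            keep &= ~((minutes >= start) & (minutes < start + length))
    return GlucoseSeries(series.timestamps[keep], series.values[keep],
                         nominal_interval=series.nominal_interval)


def _realized_gmi_quiet(
    params: PatientParams,
    config: CaseConfig,
    sensor: SensorParams,
    meals: _MealRealization,
    constants: GMIConstants,
) -> float:
    """Noise-free realized GMI: lag + sampling + quantization + clamp, no noise."""
    quiet = replace(sensor, noise_cv=0.0)
    series = sample_sensor(simulate_patient(params, config, _meals=meals), quiet, config)
    return gmi_of_mean(float(np.mean(series.values)), constants)


def calibrate_to_gmi(
    target_gmi: float,
    params: PatientParams,
    config: CaseConfig,
    sensor: SensorParams | None = None,
    tol_gmi: float = 0.05,
    max_iter: int = 50,
    constants: GMIConstants = GMI_DEFAULT,
    _meals: _MealRealization | None = None,
) -> PatientParams:
    """Bisect ``dose_scale`` until the noise-free realized GMI is within
    ``tol_gmi`` of the target.  Deterministic given the case seed (the meal
    realization is fixed before bisection and no other randomness enters).

    Raises :class:`CalibrationError` naming the achievable GMI interval when
    the target cannot be reached inside the dose_scale bounds.
    """
    sensor = sensor or SensorParams()
    if _meals is None:
        _meals = _realize_meals(config, np.random.default_rng([config.seed, _MEAL_STREAM]))
    f = lambda s: _realized_gmi_quiet(
        replace(params, dose_scale=s), config, sensor, _meals, constants
    )
    # Fixed point: if the given dose_scale already realizes the target, keep it.
    if abs(f(params.dose_scale) - target_gmi) <= tol_gmi:
        return params
    gmi_hi = f(DOSE_SCALE_MIN)   # least insulin -> highest GMI
    gmi_lo = f(DOSE_SCALE_MAX)
    if not (gmi_lo - tol_gmi <= target_gmi <= gmi_hi + tol_gmi):
        raise CalibrationError(
            f"target GMI {target_gmi:.2f}% unreachable; achievable interval is "
            f"[{gmi_lo:.2f}%, {gmi_hi:.2f}%] for dose_scale in "
            f"[{DOSE_SCALE_MIN}, {DOSE_SCALE_MAX}]"
        )
    s_lo, s_hi = DOSE_SCALE_MIN, DOSE_SCALE_MAX  # f is decreasing on [s_lo, s_hi]
    for _ in range(max_iter):
        mid = 0.5 * (s_lo + s_hi)
        g_mid = f(mid)
        if abs(g_mid - target_gmi) <= tol_gmi:
            return replace(params, dose_scale=mid)
        if g_mid > target_gmi:
            s_lo = mid
        else:
            s_hi = mid
    raise CalibrationError(
        f"calibration did not converge to GMI {target_gmi:.2f}% within {max_iter} bisections"
    )


@dataclass(frozen=True)
class CaseResult:
    config: CaseConfig
    params: PatientParams
    series: GlucoseSeries


def generate_case(
    config: CaseConfig,
    params: PatientParams | None = None,
    sensor: SensorParams | None = None,
) -> CaseResult:
    """Full per-case pipeline: realize meals, calibrate dose_scale to the
    target GMI, simulate, sample the sensor with noise, cut gaps."""
    params = params or PatientParams()
    sensor = sensor or SensorParams()
    meals = _realize_meals(config, np.random.default_rng([config.seed, _MEAL_STREAM]))
    calibrated = calibrate_to_gmi(config.target_gmi, params, config, sensor, _meals=meals)
    trace = simulate_patient(calibrated, config, _meals=meals)
    series = sample_sensor(trace, sensor, config)
    series = inject_missingness(series, config)
    return CaseResult(config=config, params=calibrated, series=series)


def generate_suite(
    n_cases: int = 10,
    gmi_low: float = 6.0,
    gmi_high: float = 9.0,
    base_seed: int = DEFAULT_BASE_SEED,
    duration_days: int = 14,
    interval_min: int = 5,
    params: PatientParams | None = None,
    sensor: SensorParams | None = None,
) -> list[tuple[CaseConfig, GlucoseSeries]]:
    """Generate a case suite with target GMIs evenly spaced from ``gmi_low``
    to ``gmi_high`` inclusive, case seeds base_seed+1 ... base_seed+n."""
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    if not gmi_low < gmi_high:
        raise ValueError("gmi_low must be < gmi_high")
    targets = np.linspace(gmi_low, gmi_high, n_cases)
    out = []
    for i, target in enumerate(targets):
        config = CaseConfig(
            case_id=f"case_{i + 1:02d}",
            duration_days=duration_days,
            interval_min=interval_min,
            target_gmi=float(target),
            seed=base_seed + i + 1,
        )
        result = generate_case(config, params=params, sensor=sensor)
        out.append((config, result.series))
    return out
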