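"""Ambulatory Glucose Profile time-of-day percentile bands.

An AGP pools all days of wear onto a single 24-hour clock and draws, for
each clock-time bin, the 5th/25th/50th/75th/95th percentiles of the pooled
readings.  The interquartile band (p25-p75) is the usual visual carrier of
within-day variability; this module also reports the clock window where the
IQR is widest, which is what a clinician scans the plot for.

Bins with no readings are flagged absent (NaN percentiles, count 0) and are
never interpolated, so a downstream narrative cannot mistake missing data
for normal glycemia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GlucoseSeries

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class AGPBands:
    """Per-bin percentile bands.  ``bin_starts_min`` are minutes after
    midnight; percentile arrays hold NaN where ``n_per_bin`` is zero."""

    bin_width_min: int
    bin_starts_min: np.ndarray
    p5: np.ndarray
    p25: np.ndarray
    p50: np.ndarray
    p75: np.ndarray
    p95: np.ndarray
    n_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts_min)

    def occupied(self) -> np.ndarray:
        return self.n_per_bin > 0

    def to_dict(self) -> dict:
        def col(a):
            return [None if np.isnan(x) else float(x) for x in a]

        return {
            "bin_width_min": self.bin_width_min,
            "bin_starts_min": [int(b) for b in self.bin_starts_min],
            "p5": col(self.p5), "p25": col(self.p25), "p50": col(self.p50),
            "p75": col(self.p75), "p95": col(self.p95),
            "n_per_bin": [int(n) for n in self.n_per_bin],
        }


@dataclass(frozen=True)
class IQRProfile:
    """Per-bin interquartile range and the clock window where it is widest."""

    iqr: np.ndarray
    max_window: tuple[int, int]  # (bin start, bin end), minutes after midnight
    max_iqr: float


def compute_bands(series: GlucoseSeries, bin_width_min: int = 60) -> AGPBands:
    """Pool readings across days by clock-time bin and take linear-interpolation
    percentiles (5, 25, 50, 75, 95) per bin."""
    if 1440 % bin_width_min:
        raise ValueError(f"bin width {bin_width_min} min does not divide 1440")
    if len(series) == 0:
        raise ValueError("compute_bands of an empty series")
    n_bins = 1440 // bin_width_min
    minutes = (
        series.timestamps.hour * 60
        + series.timestamps.minute
        + series.timestamps.second / 60.0
    )
    bins = np.minimum((np.asarray(minutes) // bin_width_min).astype(int), n_bins - 1)
    shape = (len(PERCENTILES), n_bins)
    pcts = np.full(shape, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = series.values[bins == b]
        counts[b] = len(vals)
        if len(vals):
            pcts[:, b] = np.percentile(vals, PERCENTILES, method="linear")
    return AGPBands(
        bin_width_min=bin_width_min,
        bin_starts_min=np.arange(n_bins) * bin_width_min,
        p5=pcts[0], p25=pcts[1], p50=pcts[2], p75=pcts[3], p95=pcts[4],
        n_per_bin=counts,
    )


def iqr_profile(bands: AGPBands) -> IQRProfile:
    """IQR = p75 - p25 per bin; the maximal-IQR window with earliest-clock-time
    tie-break."""
    occ = bands.occupied()
    if not occ.any():
        raise ValueError("iqr_profile: all bins are empty")
    iqr = bands.p75 - bands.p25
    candidates = np.where(occ, iqr, -np.inf)
    best = int(np.argmax(candidates))  # argmax returns the first (earliest) maximum
    start = int(bands.bin_starts_min[best])
    return IQRProfile(iqr=iqr, max_window=(start, start + bands.bin_width_min),
                      max_iqr=float(iqr[best]))


def plot_agp(bands: AGPBands, path) -> None:  # pragma: no cover - cosmetic
    """Optional AGP band plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = (bands.bin_starts_min + bands.bin_width_min / 2) / 60.0
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.fill_between(t, bands.p5, bands.p95, alpha=0.2, label="5-95%")
    ax.fill_between(t, bands.p25, bands.p75, alpha=0.4, label="25-75%")
    ax.plot(t, bands.p50, lw=2, label="median")
    ax.axhspan(70, 180, color="green", alpha=0.08)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_xlim(0, 24)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
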