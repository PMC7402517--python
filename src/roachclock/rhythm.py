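"""Rhythm analysis: chi-square periodogram, smoothing, classification, period estimates.

Implements the locomotor-rhythm analysis conventions used for cockroach
running-wheel data: the Sokolove–Bushell chi-square periodogram over
candidate periods 18–30 h, second-order Savitzky–Golay smoothing (window
11), a very conservative significance level (alpha = 1e-6), the
most-prominent-peak rule for the circadian period tau, the >= 1 h two-peak
rule for desynchronization, and the period change delta tau = tau_after -
tau_before.  A peak-to-peak estimator for smooth model output is included
for measuring the period of simulated clockwork signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import chi2

__all__ = [
    "ActivityRecord",
    "Periodogram",
    "PeriodEstimate",
    "RhythmClassification",
    "estimate_period_peaks",
    "chi_square_periodogram",
    "smooth_periodogram",
    "classify_rhythmicity",
    "delta_period",
    "ArrhythmicError",
]

#: default candidate-period range scanned by the periodogram (hours)
DEFAULT_PERIOD_RANGE = (18.0, 30.0)
#: default candidate-period grid step (hours)
DEFAULT_PERIOD_STEP = 0.1
#: default per-period significance level
DEFAULT_ALPHA = 1e-6
#: Savitzky-Golay defaults applied to periodograms
SG_WINDOW = 11
SG_ORDER = 2
#: two significant peaks at least this far apart (hours) indicate desynchronization
DESYNC_SEPARATION = 1.0
#: peak/threshold ratio separating strong from weak rhythms (proxy convention)
STRONG_RATIO = 2.0


class ArrhythmicError(ValueError):
    """An operation that needs a determinable period received an arrhythmic input."""


@dataclass
class ActivityRecord:
    """Binned running-wheel counts: bin start times (hours) and event counts."""

    times: np.ndarray
    counts: np.ndarray
    bin_width: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("bin start times must be strictly increasing")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        steps = np.diff(self.times)
        if steps.size and not np.allclose(steps, self.bin_width, rtol=1e-6, atol=1e-9):
            raise ValueError("bins must be uniform and match the declared bin width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        return self.times.size * self.bin_width

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, "count": self.counts})


@dataclass
class Periodogram:
    """Chi-square periodogram: statistic and significance threshold per candidate period."""

    periods: np.ndarray  # hours, strictly increasing
    statistic: np.ndarray  # Q_P per period
    threshold: np.ndarray  # chi-square quantile at 1 - alpha, df = columns - 1
    alpha: float
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        if np.any(np.diff(self.periods) <= 0):
            raise ValueError("candidate periods must be strictly increasing")
        if np.any(self.threshold <= 0):
            raise ValueError("significance thresholds must be positive")

    @property
    def is_smoothed(self) -> bool:
        return self.smoothed is not None

    def to_frame(self):
        import pandas as pd

        data = {"period_h": self.periods, "Q": self.statistic, "threshold": self.threshold}
        if self.smoothed is not None:
            data["Q_smoothed"] = self.smoothed
        return pd.DataFrame(data)


@dataclass
class PeriodEstimate:
    """Point estimate of an oscillation period and how it was obtained."""

    period: float  # hours
    method: str  # "peak-to-peak" | "autocorrelation" | "periodogram"
    n_cycles: int
    dispersion: float  # std of cycle lengths (hours)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class RhythmClassification:
    """Labels per the behavioural taxonomy plus the dominant period."""

    rhythmic: bool
    strength: str  # "strong" | "weak" | "n/a"
    synchrony: str  # "synchronized" | "desynchronized"
    dominant_period: float | None  # hours; present iff rhythmic
    secondary_periods: tuple[float, ...] = ()

    @property
    def rhythmicity(self) -> str:
        return "rhythmic" if self.rhythmic else "arrhythmic"


def _refine_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by a quadratic through (i-1, i, i+1); returns index offset."""
    if i == 0 or i == y.size - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))


def estimate_period_peaks(
    signal: np.ndarray,
    sample_step: float,
    transient_discard: float = 200.0,
    min_cycles: int = 3,
    prominence_frac: float = 0.1,
) -> PeriodEstimate:
    """Period of a uniformly sampled smooth signal from successive maxima.

    The first ``transient_discard`` hours are dropped, local maxima with
    prominence at least ``prominence_frac`` of the remaining signal range are
    located and refined by a local quadratic fit, and the period is the mean
    spacing of successive maxima.

    Raises
    ------
    ArrhythmicError
        if fewer than ``min_cycles`` complete cycles (inter-peak intervals)
        are found after the transient.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    start = int(round(transient_discard / sample_step))
    if start >= signal.size:
        raise ValueError("transient discard exceeds the signal length")
    y = signal[start:]
    span = float(np.ptp(y))
    if span == 0.0:
        raise ArrhythmicError("signal is constant after the transient")
    peaks, _ = find_peaks(y, prominence=prominence_frac * span)
    if peaks.size < min_cycles + 1:
        raise ArrhythmicError(
            f"found {peaks.size} maxima, need at least {min_cycles + 1} for {min_cycles} cycles"
        )
    refined = np.array([p + _refine_peak(y, p) for p in peaks]) * sample_step
    gaps = np.diff(refined)
    return PeriodEstimate(
        period=float(np.mean(gaps)),
        method="peak-to-peak",
        n_cycles=int(gaps.size),
        dispersion=float(np.std(gaps)),
    )


def estimate_period_autocorr(
    signal: np.ndarray,
    sample_step: float,
    transient_discard: float = 200.0,
    min_lag: float = 1.0,
) -> PeriodEstimate:
    """Period from the first prominent maximum of the autocorrelation function.

    Serves as an independent cross-check of :func:`estimate_period_peaks`.
    """
    signal = np.asarray(signal, dtype=float)
    start = int(round(transient_discard / sample_step))
    y = signal[start:] - np.mean(signal[start:])
    if np.ptp(y) == 0.0:
        raise ArrhythmicError("signal is constant after the transient")
    ac = np.correlate(y, y, mode="full")[y.size - 1 :]
    ac /= ac[0]
    lag0 = int(round(min_lag / sample_step))
    peaks, props = find_peaks(ac[lag0:], prominence=0.05)
    if peaks.size == 0:
        raise ArrhythmicError("no autocorrelation peak found")
    i = lag0 + peaks[np.argmax(props["prominences"])]
    lag = (i + _refine_peak(ac, i)) * sample_step
    return PeriodEstimate(period=float(lag), method="autocorrelation", n_cycles=1, dispersion=0.0)


def chi_square_periodogram(
    activity: ActivityRecord,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    period_step: float = DEFAULT_PERIOD_STEP,
    alpha: float = DEFAULT_ALPHA,
) -> Periodogram:
    """Sokolove–Bushell chi-square periodogram of a binned activity record.

    For each candidate period ``P`` the record is folded into ``K =
    round(P / bin_width)`` columns using only complete rows; the statistic

        Q_P = R * sum_h (M_h - M)^2 / s^2,

    with ``M_h`` the column means over ``R`` rows, ``M`` the grand mean and
    ``s^2`` the (population) variance of the folded points, follows a
    chi-square law with ``K - 1`` degrees of freedom for exchangeable noise.
    The per-period threshold is the ``1 - alpha`` chi-square quantile.
    """
    lo, hi = period_range
    if not 0 < lo < hi:
        raise ValueError("period range must satisfy 0 < min < max")
    n = activity.counts.size
    if n * activity.bin_width < 2.0 * hi:
        raise ValueError("record must cover at least two times the longest candidate period")
    periods = np.round(np.arange(lo, hi + 0.5 * period_step, period_step), 10)
    x = activity.counts.astype(float)
    stat = np.empty(periods.size)
    thr = np.empty(periods.size)
    for k, p in enumerate(periods):
        cols = int(round(p / activity.bin_width))
        rows = n // cols
        folded = x[: rows * cols].reshape(rows, cols)
        grand = folded.mean()
        denom = np.mean((folded - grand) ** 2)
        if denom == 0.0:
            stat[k] = 0.0
        else:
            col_means = folded.mean(axis=0)
            stat[k] = rows * np.sum((col_means - grand) ** 2) / denom
        thr[k] = chi2.ppf(1.0 - alpha, df=cols - 1)
    return Periodogram(periods=periods, statistic=stat, threshold=thr, alpha=alpha)


def smooth_periodogram(pg: Periodogram, window: int = SG_WINDOW, order: int = SG_ORDER) -> Periodogram:
    """Savitzky–Golay smoothing of the periodogram statistic.

    Interior points use the standard convolution filter; the first and last
    half-windows are refit on truncated windows (no padding), so no values
    are fabricated beyond the scanned period range.
    """
    if window % 2 != 1 or window <= order + 1:
        raise ValueError("window must be odd and larger than the polynomial order")
    q = np.asarray(pg.statistic, dtype=float)
    if q.size < window:
        raise ValueError(f"need at least {window} candidate periods to smooth")
    sm = savgol_filter(q, window_length=window, polyorder=order, mode="interp")
    half = window // 2
    idx = np.arange(q.size)
    for i in range(half):
        w = slice(0, i + half + 1)
        sm[i] = np.polynomial.polynomial.Polynomial.fit(idx[w], q[w], order)(i)
        j = q.size - 1 - i
        w = slice(j - half, q.size)
        sm[j] = np.polynomial.polynomial.Polynomial.fit(idx[w], q[w], order)(j)
    return Periodogram(
        periods=pg.periods.copy(),
        statistic=q.copy(),
        threshold=pg.threshold.copy(),
        alpha=pg.alpha,
        smoothed=sm,
    )


def significant_peaks(pg: Periodogram) -> list[tuple[float, float, float]]:
    """Supra-threshold local maxima of the smoothed statistic.

    Returns (period, smoothed statistic, threshold) sorted by decreasing
    prominence ratio (statistic / threshold).  Grid endpoints count as peaks
    when they top their single neighbour.
    """
    if not pg.is_smoothed:
        raise ValueError("periodogram must be smoothed before peak extraction")
    s = pg.smoothed
    peaks = list(find_peaks(s)[0])
    if s.size >= 2 and s[0] > s[1]:
        peaks.insert(0, 0)
    if s.size >= 2 and s[-1] > s[-2]:
        peaks.append(s.size - 1)
    out = [
        (float(pg.periods[i]), float(s[i]), float(pg.threshold[i]))
        for i in peaks
        if s[i] > pg.threshold[i]
    ]
    out.sort(key=lambda rec: rec[1] / rec[2], reverse=True)
    return out


def classify_rhythmicity(
    pg_full: Periodogram,
    pg_segments: tuple[Periodogram, ...] = (),
    strong_ratio: float = STRONG_RATIO,
    desync_separation: float = DESYNC_SEPARATION,
) -> RhythmClassification:
    """Label a record rhythmic/arrhythmic, strong/weak, synchronized/desynchronized.

    Rhythmic means at least one supra-threshold peak in the smoothed
    full-record periodogram; the circadian period tau is the most prominent
    such peak.  Desynchronization requires two supra-threshold peaks at least
    ``desync_separation`` hours apart in the full record AND a segment
    periodogram showing two such components (the segment requirement stands
    in for by-eye inspection of the actogram).  Strength is a proxy
    convention: strong iff the dominant peak exceeds ``strong_ratio`` times
    its threshold.
    """
    peaks = significant_peaks(pg_full)
    if not peaks:
        return RhythmClassification(
            rhythmic=False, strength="n/a", synchrony="synchronized", dominant_period=None
        )
    dominant = peaks[0]
    secondary = tuple(p[0] for p in peaks[1:])

    def has_separated_pair(records: list[tuple[float, float, float]]) -> bool:
        ps = [r[0] for r in records]
        return any(
            abs(a - b) >= desync_separation for i, a in enumerate(ps) for b in ps[i + 1 :]
        )

    desync = has_separated_pair(peaks) and any(
        has_separated_pair(significant_peaks(seg)) for seg in pg_segments
    )
    strength = "strong" if dominant[1] / dominant[2] >= strong_ratio else "weak"
    return RhythmClassification(
        rhythmic=True,
        strength=strength,
        synchrony="desynchronized" if desync else "synchronized",
        dominant_period=dominant[0],
        secondary_periods=secondary,
    )


def delta_period(before: RhythmClassification, after: RhythmClassification) -> float:
    """Period change delta tau = tau_after - tau_before (hours).

    Undefined when either side is arrhythmic; such animals are excluded from
    period-change comparisons.
    """
    if not before.rhythmic or not after.rhythmic:
        raise ArrhythmicError("delta tau requires a determinable period on both sides")
    return float(after.dominant_period - before.dominant_period)
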