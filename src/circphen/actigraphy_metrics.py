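"""Nonparametric rest-activity rhythm metrics and diary-anchored sleep variables.

Implements the standard nonparametric circadian toolbox on epoch-level wrist
activity counts:

* the average 24 h profile (clock-time-binned mean across days),
* M10 / L5 — the most active contiguous 10 h and least active 5 h windows of
  that profile (circular, wrapping midnight), and their difference, the
  rhythm amplitude,
* interdaily stability IS = (n * sum_h (xbar_h - xbar)^2) /
  (p * sum_i (x_i - xbar)^2) with p bins per day and n total bins — the
  fraction of variance explained by the average daily pattern, in [0, 1],
* intradaily variability IV = (n * sum_{i>=2} (x_i - x_{i-1})^2) /
  ((n - 1) * sum_i (x_i - xbar)^2) — the normalized mean squared successive
  difference, higher = more fragmented,

plus sleep summaries scored against diary rest intervals: an epoch within the
rest interval counts as sleep when its activity is below a wake threshold.
Clock-time summaries (bedtime, waketime, midsleep) are circular means so
times straddling midnight average correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import circular_mean_hours
from .errors import DegenerateInputError

WAKE_THRESHOLD_DEFAULT = 40.0  # counts/epoch
MIN_DAY_COVERAGE = 0.8         # days with less epoch coverage are dropped


@dataclass
class RhythmMetrics:
    m10_start: float            # clock hours
    m10_mean: float             # counts
    l5_start: float
    l5_mean: float
    amplitude: float            # m10_mean - l5_mean
    relative_amplitude: float   # (M10-L5)/(M10+L5), extra output
    interdaily_stability: float
    intradaily_variability: float


@dataclass
class SleepSummary:
    bedtime: float              # circular mean clock hours
    waketime: float
    midsleep: float
    total_sleep_time: float     # hours
    sleep_efficiency: float     # percent
    waso: float                 # minutes
    n_nights: int


# ---------------------------------------------------------------------------
# binning and the 24 h profile
# ---------------------------------------------------------------------------

def bin_series(series, bin_minutes: int = 60) -> np.ndarray:
    """Rebin an epoch series to coarser bins (mean counts per bin), in time order."""
    if (bin_minutes % series.epoch_minutes) != 0:
        raise ValueError("bin_minutes must be a multiple of the epoch length")
    k = bin_minutes // series.epoch_minutes
    n = (len(series.counts) // k) * k
    if n == 0:
        raise ValueError("series shorter than one bin")
    return np.asarray(series.counts[:n], dtype=float).reshape(-1, k).mean(axis=1)


def average_profile(series, bin_minutes: int = 30) -> np.ndarray:
    """Mean activity per clock-time bin across days (the average 24 h profile).

    Bins are aligned to clock time regardless of when the recording starts
    (bin 0 covers 00:00). Recording days (24 h chunks from the first epoch)
    covering less than 80% of their epochs are excluded. Requires at least
    one full day of data.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    counts = np.asarray(series.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty activity series")
    starts = np.asarray(series.epoch_start_hours, dtype=float)
    epochs_per_day = 1440 // series.epoch_minutes
    n_days = counts.size // epochs_per_day
    if n_days < 1:
        raise ValueError("need at least one full day of data")
    n = n_days * epochs_per_day
    counts, starts = counts[:n], starts[:n]
    day = np.floor((starts - starts[0]) / 24.0 + 1e-9).astype(int)
    coverage = np.array([(~np.isnan(counts[day == d])).mean() for d in range(n_days)])
    keep = coverage >= MIN_DAY_COVERAGE
    if not keep.any():
        raise ValueError("no day passes the coverage requirement")
    use = keep[day] & ~np.isnan(counts)
    n_bins = 1440 // bin_minutes
    bin_idx = np.floor((starts % 24.0) / (bin_minutes / 60.0) + 1e-9).astype(int) % n_bins
    sums = np.bincount(bin_idx[use], weights=counts[use], minlength=n_bins)
    nobs = np.bincount(bin_idx[use], minlength=n_bins)
    if np.any(nobs == 0):
        raise ValueError("empty clock-time bins in average profile")
    return sums / nobs


# ---------------------------------------------------------------------------
# M10 / L5 / amplitude
# ---------------------------------------------------------------------------

def _window_means(profile: np.ndarray, window_bins: int) -> np.ndarray:
    """Mean of every contiguous circular window; O(n) via a wrapped cumulative sum."""
    ext = np.concatenate([profile, profile[: window_bins - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[window_bins:] - csum[:-window_bins])[: len(profile)] / window_bins


def m10_l5_amplitude(profile: np.ndarray, bin_minutes: int = 30):
    """M10/L5 window phases and means plus amplitude from a 24 h profile.

    Windows wrap midnight; ties resolve to the earliest start from 00:00.
    Returns a dict with m10_start/m10_mean/l5_start/l5_mean/amplitude/
    relative_amplitude.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size * bin_minutes != 1440:
        raise ValueError("profile must cover exactly 24 h at the stated bin size")
    bins_per_hour = 60 / bin_minutes
    w10 = int(round(10 * bins_per_hour))
    w5 = int(round(5 * bins_per_hour))
    means10 = _window_means(profile, w10)
    means5 = _window_means(profile, w5)
    i10 = int(np.argmax(means10))   # argmax/argmin take the first = earliest
    i5 = int(np.argmin(means5))
    m10_mean, l5_mean = float(means10[i10]), float(means5[i5])
    denom = m10_mean + l5_mean
    return {
        "m10_start": i10 / bins_per_hour,
        "m10_mean": m10_mean,
        "l5_start": i5 / bins_per_hour,
        "l5_mean": l5_mean,
        "amplitude": m10_mean - l5_mean,
        "relative_amplitude": (m10_mean - l5_mean) / denom if denom > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# IS / IV
# ---------------------------------------------------------------------------

def interdaily_stability(series, bin_minutes: int = 60) -> float:
    """Interdaily stability on hourly bins (by default); in [0, 1]."""
    x = bin_series(series, bin_minutes)
    p = 1440 // bin_minutes
    n_days = x.size // p
    if n_days < 2:
        raise ValueError("need at least 2 full days for interdaily stability")
    x = x[: n_days * p]
    n = x.size
    xbar = x.mean()
    total_ss = np.sum((x - xbar) ** 2)
    if total_ss == 0:
        raise DegenerateInputError("constant series: interdaily stability undefined")
    hourly_means = x.reshape(n_days, p).mean(axis=0)
    return float(n * np.sum((hourly_means - xbar) ** 2) / (p * total_ss))


def intradaily_variability(series, bin_minutes: int = 60) -> float:
    """Intradaily variability on hourly bins (by default); >= 0."""
    x = bin_series(series, bin_minutes)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 bins for intradaily variability")
    xbar = x.mean()
    total_ss = np.sum((x - xbar) ** 2)
    if total_ss == 0:
        raise DegenerateInputError("constant series: intradaily variability undefined")
    return float(n * np.sum(np.diff(x) ** 2) / ((n - 1) * total_ss))


def rhythm_metrics(series, profile_bin_minutes: int = 30,
                   isiv_bin_minutes: int = 60) -> RhythmMetrics:
    """All nonparametric rhythm metrics for one activity series."""
    prof = average_profile(series, profile_bin_minutes)
    win = m10_l5_amplitude(prof, profile_bin_minutes)
    return RhythmMetrics(
        m10_start=win["m10_start"], m10_mean=win["m10_mean"],
        l5_start=win["l5_start"], l5_mean=win["l5_mean"],
        amplitude=win["amplitude"], relative_amplitude=win["relative_amplitude"],
        interdaily_stability=interdaily_stability(series, isiv_bin_minutes),
        intradaily_variability=intradaily_variability(series, isiv_bin_minutes),
    )


# ---------------------------------------------------------------------------
# sleep summaries
# ---------------------------------------------------------------------------

def sleep_summary(series, rest_intervals=None,
                  wake_threshold: float = WAKE_THRESHOLD_DEFAULT) -> SleepSummary:
    """Diary-anchored sleep variables averaged across nights.

    Within each diary rest interval an epoch is scored asleep when its counts
    fall below ``wake_threshold``. Per night: total sleep time = asleep
    epochs x epoch length; WASO = awake epochs after the first sleep epoch;
    efficiency = 100 * TST / interval duration. Bedtime/waketime come from the
    diary verbatim; midsleep is the interval midpoint. Clock-time summaries
    are circular means across nights.
    """
    rest_intervals = series.rest_intervals if rest_intervals is None else rest_intervals
    if not rest_intervals:
        raise ValueError("no rest intervals provided")
    starts = np.asarray(series.epoch_start_hours, dtype=float)
    counts = np.asarray(series.counts, dtype=float)
    epoch_h = series.epoch_minutes / 60.0
    span_end = starts[-1] + epoch_h

    beds, wakes, mids, tsts, ses, wasos = [], [], [], [], [], []
    for bed, wake in rest_intervals:
        if bed < starts[0] - 1e-9 or wake > span_end + 1e-9:
            continue  # diary interval outside the recording; skip
        centers = starts + epoch_h / 2.0
        mask = (centers >= bed) & (centers < wake)
        n_epochs = int(mask.sum())
        if n_epochs == 0:
            continue
        asleep = counts[mask] < wake_threshold
        tst = asleep.sum() * epoch_h
        duration = wake - bed
        first_sleep = np.argmax(asleep) if asleep.any() else None
        waso_min = 0.0
        if first_sleep is not None:
            waso_min = float((~asleep[first_sleep:]).sum() * series.epoch_minutes)
        beds.append(bed % 24.0)
        wakes.append(wake % 24.0)
        mids.append((bed + duration / 2.0) % 24.0)
        tsts.append(tst)
        ses.append(100.0 * tst / duration)
        wasos.append(waso_min)

    if not beds:
        raise ValueError("no usable rest intervals within the recording")
    return SleepSummary(
        bedtime=circular_mean_hours(beds),
        waketime=circular_mean_hours(wakes),
        midsleep=circular_mean_hours(mids),
        total_sleep_time=float(np.mean(tsts)),
        sleep_efficiency=float(np.mean(ses)),
        waso=float(np.mean(wasos)),
        n_nights=len(beds),
    )
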