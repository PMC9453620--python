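"""Circular (clock-time) statistics helpers.

Clock times are real hours; statistics treat them as angles on a 24 h circle
so that e.g. bedtimes of 23:30 and 00:30 average to 00:00 rather than 12:00.
"""

from __future__ import annotations

import numpy as np

HOURS_PER_DAY = 24.0
_TO_RAD = 2.0 * np.pi / HOURS_PER_DAY


def circular_mean_hours(hours) -> float:
    """Circular mean of clock times, in [0, 24)."""
    h = np.asarray(hours, dtype=float)
    if h.size == 0:
        raise ValueError("empty input")
    ang = h * _TO_RAD
    mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean / _TO_RAD) % HOURS_PER_DAY)


def unwrap_hours(hours, center: float | None = None):
    """Map clock times onto a continuous scale centered on ``center``.

    Returns values in [center - 12, center + 12), so a set of times clustered
    around e.g. 23:30 becomes {..., 23.4, 24.6, ...} instead of wrapping to
    0.6 — required before feeding clock times to linear statistics. When
    ``center`` is None the circular mean of the input is used.
    """
    h = np.asarray(hours, dtype=float)
    if center is None:
        center = circular_mean_hours(h[np.isfinite(h)])
    return (h - center + 12.0) % HOURS_PER_DAY + center - 12.0


def circular_sd_hours(hours) -> float:
    """Circular standard deviation of clock times, in hours.

    Uses the standard definition sqrt(-2 ln R) on the mean resultant length R,
    mapped back to hours. Zero for identical times.
    """
    h = np.asarray(hours, dtype=float)
    if h.size == 0:
        raise ValueError("empty input")
    ang = h * _TO_RAD
    r = np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    r = min(float(r), 1.0)
    if r <= 0.0:
        return HOURS_PER_DAY / 2.0
    return float(np.sqrt(-2.0 * np.log(r)) / _TO_RAD)
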