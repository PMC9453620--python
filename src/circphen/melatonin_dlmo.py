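"""Dim-light melatonin onset (DLMO) from evening saliva profiles.

DLMO is the evening time at which melatonin first sustainably crosses a
threshold. Saliva melatonin runs proportionally lower than plasma, so the
saliva threshold is calibrated from paired saliva/plasma draws to be the
saliva concentration equivalent to 10 pg/mL of plasma melatonin. Profiles
must show the canonical "hockey stick" (flat baseline, then a sustained
rise) to yield a valid onset; a deterministic QC rule encodes that shape
requirement. The onset itself is found by linear interpolation between the
last sub-threshold sample and the first at/above threshold.

Times are session-relative monotone hours (24.5 = 00:30 after midnight), so
interpolation never spans a clock wrap; report mod 24 for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError

PLASMA_EQUIVALENT_DEFAULT = 10.0  # pg/mL
MIN_SAMPLES = 4
SUSTAIN_SAMPLES = 2  # consecutive at/above-threshold samples required


@dataclass
class DlmoResult:
    subject_id: str
    threshold: float       # pg/mL, saliva scale
    dlmo_time: float       # session-relative hours; NaN if QC failed
    qc_pass: bool
    qc_reason: str


def calibrate_threshold(pairs, plasma_equivalent: float = PLASMA_EQUIVALENT_DEFAULT) -> float:
    """Assay-specific saliva threshold from paired (saliva, plasma) samples.

    threshold = plasma_equivalent * mean_i(saliva_i / plasma_i), i.e. the mean
    of per-pair ratios (not the ratio of means).
    """
    pairs = list(pairs)
    if not pairs:
        raise CalibrationError("no saliva/plasma pairs provided")
    ratios = []
    for saliva, plasma in pairs:
        if plasma <= 0:
            raise CalibrationError(f"non-positive plasma concentration {plasma!r}")
        ratios.append(saliva / plasma)
    if plasma_equivalent <= 0:
        raise CalibrationError("plasma_equivalent must be > 0")
    return float(plasma_equivalent * np.mean(ratios))


def _sustained_crossing_index(conc: np.ndarray, threshold: float):
    """Index of the first at/above-threshold sample of the sustained rise.

    The sustained rise is the final run of at/above-threshold samples, i.e.
    everything after the last sub-threshold sample; earlier transient
    crossings are ignored. Returns None if the series never ends above
    threshold.
    """
    below = conc < threshold
    if not below.any():
        return 0  # already above from the first sample
    last_below = int(np.nonzero(below)[0][-1])
    if last_below == len(conc) - 1:
        return None
    return last_below + 1


def qc_profile(profile, threshold: float):
    """Check the hockey-stick shape required for a valid DLMO.

    Pass requires (a) at least one strictly sub-threshold sample before the
    rise, (b) at least two consecutive at/above-threshold samples in the rise
    and (c) no return below threshold afterwards. Returns (qc_pass, reason);
    reason is one of "ok", "insufficient_samples", "onset_before_sampling",
    "no_crossing", "unsustained_crossing".
    """
    conc = np.asarray(profile.concentrations, dtype=float)
    if conc.size < MIN_SAMPLES:
        return False, "insufficient_samples"
    up_cross = np.any((conc[:-1] < threshold) & (conc[1:] >= threshold))
    if not up_cross:
        return False, "no_crossing"
    if conc[0] >= threshold:
        return False, "onset_before_sampling"
    idx = _sustained_crossing_index(conc, threshold)
    if idx is None or conc.size - idx < SUSTAIN_SAMPLES:
        return False, "unsustained_crossing"
    return True, "ok"


def compute_dlmo(profile, threshold: float) -> float:
    """Onset time by linear interpolation at the sustained threshold crossing.

    t = t0 + (thr - c0) * (t1 - t0) / (c1 - c0), where (t0, c0) is the last
    sub-threshold sample and (t1, c1) the first at/above-threshold sample of
    the sustained rise. A sample exactly at threshold is its own onset.
    """
    conc = np.asarray(profile.concentrations, dtype=float)
    times = np.asarray(profile.times, dtype=float)
    if conc[0] >= threshold:
        raise ValueError("onset_before_sampling: first sample already at/above threshold")
    idx = _sustained_crossing_index(conc, threshold)
    if idx is None or idx == 0:
        raise ValueError("no sustained threshold crossing in profile")
    t0, c0 = times[idx - 1], conc[idx - 1]
    t1, c1 = times[idx], conc[idx]
    return float(t0 + (threshold - c0) * (t1 - t0) / (c1 - c0))


def dlmo_for_profile(profile, threshold: float) -> DlmoResult:
    """QC a profile and, if valid, compute its DLMO."""
    ok, reason = qc_profile(profile, threshold)
    if not ok:
        return DlmoResult(profile.subject_id, threshold, float("nan"), False, reason)
    return DlmoResult(profile.subject_id, threshold,
                      compute_dlmo(profile, threshold), True, "ok")
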