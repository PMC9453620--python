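"""Seeded simulation of a multimodal circadian-phenotyping cohort.

Every modality is driven by a single latent per-subject quantity, the phase
offset ``delta`` (hours, positive = advanced internal clock). An advanced
subject peaks earlier in gene expression, has an earlier melatonin onset,
goes to bed and rises earlier, and scores higher on the
Morningness-Eveningness Questionnaire (MEQ). This shared latent trait is what
lets the downstream agreement analyses be validated against ground truth.

Generative models
-----------------
expression   x_g(t) = m_g + A_g * cos(2*pi*(t - (phi_g - delta))/24) + eps
melatonin    plasma(t) = baseline + rise_rate * max(0, t - DLMO_s),
             DLMO_s = dlmo_base - delta; saliva = ratio * plasma + noise
activity     square wave (day level during wake, night level during rest,
             rest shifted earlier by delta) plus noise and brief intrusions
             whose rate is governed by ``fragmentation``
MEQ          score = round(intercept + slope * delta + noise), clipped to
             the instrument's range [16, 86]

Reproducibility: one seed per cohort; each subject's random stream is derived
from (cohort seed, sha256(subject_id)), so enlarging a cohort never perturbs
subjects already generated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np

from .errors import ConfigError

MEQ_MIN, MEQ_MAX = 16, 86
MORNING_CUTOFF = 59  # score >= 59 -> morning type
EVENING_CUTOFF = 41  # score <= 41 -> evening type

_CHRONOTYPES = ("morning", "intermediate", "evening")
_PANEL_STREAM_KEY = 0x9E3779B9


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """All tunable knobs of the cohort generator.

    Defaults emulate the study design this package validates: 40 older adults,
    morning-leaning chronotype mix, blood draws at ~8 pm and ~10 am, hourly
    evening saliva sampling, and 7 days of 1-min wrist actigraphy.
    """

    n_subjects: int = 40
    seed: int = 0

    # latent circadian phase offset (hours; positive = advanced)
    phase_offset_sd: float = 1.0
    phase_offset_mean_by_type: dict = field(
        default_factory=lambda: {"morning": 2.7, "intermediate": 0.0, "evening": -2.7}
    )
    chronotype_weights: dict = field(
        default_factory=lambda: {"morning": 0.7, "intermediate": 0.3, "evening": 0.0}
    )

    # demographics
    age_mean: float = 71.2
    age_sd: float = 4.2
    female_fraction: float = 0.53

    # gene expression (log-scale arbitrary units)
    # panel_seed fixes the per-gene cosinor parameters independently of the
    # cohort seed: gene rhythms are biology shared by every cohort, which is
    # what lets a clock trained on one cohort transfer to another.
    panel_seed: int = 7
    n_genes: int = 40
    gene_mesor_mean: float = 7.0
    gene_mesor_sd: float = 1.0
    gene_amplitude_mean: float = 2.0
    gene_amplitude_sd: float = 0.4
    gene_noise_sd: float = 1.0
    pm_sample_time: float = 20.0
    am_sample_time: float = 10.0
    sample_time_jitter_sd: float = 0.5
    # "visit": evening/morning study-visit draws; "uniform": two suitably
    # spaced draws at a uniform time of day, emulating the round-the-clock
    # time-course data a clock is trained on. Training cohorts need the
    # latter: with all draws at the same two clock times, sampling-time
    # variance is dwarfed by phase-offset variance and regression to the
    # mean attenuates the very signal the clock must learn.
    sample_times_mode: str = "visit"

    # melatonin (pg/mL; session-relative hours, may run past midnight)
    melatonin_baseline: float = 2.0
    melatonin_rise_rate: float = 8.0
    saliva_plasma_ratio_true: float = 0.3
    dlmo_base: float = 20.6
    saliva_noise_sd: float = 0.5
    plasma_noise_sd: float = 0.0
    melatonin_sampling_start: float = 18.0
    melatonin_sampling_end: float = 25.0
    melatonin_sampling_interval: float = 1.0

    # actigraphy
    n_days: int = 7
    epoch_minutes: int = 1
    activity_day_level: float = 300.0
    activity_night_level: float = 10.0
    activity_noise_sd: float = 50.0
    fragmentation: float = 0.15
    bedtime_base: float = 22.75
    waketime_base: float = 7.083
    sleep_time_jitter_sd: float = 0.25
    intrusion_rate_per_minute: float = 0.02
    intrusion_mean_minutes: float = 10.0

    # MEQ
    meq_intercept: float = 53.0
    meq_slope: float = 6.0
    meq_noise_sd: float = 3.0

    def validate(self) -> None:
        def require(cond, fld, msg):
            if not cond:
                raise ConfigError(fld, msg)

        require(int(self.n_subjects) >= 0, "n_subjects", "must be >= 0")
        require(int(self.n_genes) >= 1, "n_genes", "must be >= 1")
        require(int(self.n_days) >= 1, "n_days", "must be >= 1")
        require(int(self.epoch_minutes) >= 1 and 60 % int(self.epoch_minutes) == 0,
                "epoch_minutes", "must be a positive divisor of 60")
        require(0.0 <= self.fragmentation <= 1.0, "fragmentation", "must be in [0, 1]")
        for fld in ("phase_offset_sd", "gene_noise_sd", "saliva_noise_sd",
                    "plasma_noise_sd", "activity_noise_sd", "meq_noise_sd",
                    "sample_time_jitter_sd", "sleep_time_jitter_sd",
                    "gene_amplitude_sd", "gene_mesor_sd", "age_sd"):
            require(getattr(self, fld) >= 0.0, fld, "must be >= 0")
        require(self.saliva_plasma_ratio_true > 0, "saliva_plasma_ratio_true",
                "must be > 0")
        require(self.melatonin_rise_rate > 0, "melatonin_rise_rate", "must be > 0")
        require(self.melatonin_baseline >= 0, "melatonin_baseline", "must be >= 0")
        require(self.melatonin_sampling_end > self.melatonin_sampling_start,
                "melatonin_sampling_end", "must exceed melatonin_sampling_start")
        require(self.melatonin_sampling_interval > 0, "melatonin_sampling_interval",
                "must be > 0")
        require(self.activity_day_level >= 0, "activity_day_level", "must be >= 0")
        require(self.activity_night_level >= 0, "activity_night_level", "must be >= 0")
        require(0.0 <= self.female_fraction <= 1.0, "female_fraction",
                "must be in [0, 1]")
        require(self.intrusion_rate_per_minute >= 0, "intrusion_rate_per_minute",
                "must be >= 0")
        require(self.intrusion_mean_minutes >= 1, "intrusion_mean_minutes",
                "must be >= 1")
        for label in _CHRONOTYPES:
            require(label in self.phase_offset_mean_by_type,
                    "phase_offset_mean_by_type", f"missing chronotype {label!r}")
            require(label in self.chronotype_weights,
                    "chronotype_weights", f"missing chronotype {label!r}")
        w = np.array([self.chronotype_weights[c] for c in _CHRONOTYPES], float)
        require(np.all(w >= 0) and w.sum() > 0, "chronotype_weights",
                "weights must be nonnegative and sum to > 0")
        for t in (self.pm_sample_time, self.am_sample_time):
            require(0.0 <= t < 24.0, "pm_sample_time/am_sample_time",
                    "sample times must lie in [0, 24)")
        require(self.sample_times_mode in ("visit", "uniform"),
                "sample_times_mode", "must be 'visit' or 'uniform'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        for k in d:
            if k not in known:
                raise ConfigError(k, "unknown configuration field")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_config(**overrides) -> CohortConfig:
    """The study-emulating default configuration, with optional overrides."""
    cfg = replace(CohortConfig(), **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSample:
    subject_id: str
    clock_time: float          # hours in [0, 24)
    session: str               # "AM" | "PM"
    values: np.ndarray         # one per gene, log-scale units


@dataclass
class MelatoninProfile:
    subject_id: str
    medium: str                # "saliva" | "plasma"
    times: np.ndarray          # session-relative hours, strictly increasing
    concentrations: np.ndarray  # pg/mL, >= 0


@dataclass
class ActivitySeries:
    subject_id: str
    epoch_start_hours: np.ndarray  # hours since recording start
    epoch_minutes: int
    counts: np.ndarray             # >= 0
    rest_intervals: list           # [(bed_hours, wake_hours)] absolute, per night


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    sex: int                       # 1 = female, 0 = male
    phase_offset_delta: float      # hours; > 0 = advanced phase
    meq_score: int
    chronotype_label: str
    expression_samples: list = field(default_factory=list)
    melatonin_saliva: Optional[MelatoninProfile] = None
    melatonin_plasma: Optional[MelatoninProfile] = None
    activity: Optional[ActivitySeries] = None
    true_dlmo: Optional[float] = None  # ground truth, session-relative hours


@dataclass
class GenePanel:
    gene_ids: list
    mesor: np.ndarray       # m_g
    amplitude: np.ndarray   # A_g
    acrophase: np.ndarray   # phi_g, hours in [0, 24)


@dataclass
class Cohort:
    config: CohortConfig
    gene_panel: GenePanel
    subjects: list

    def __len__(self):
        return len(self.subjects)


# ---------------------------------------------------------------------------
# random-stream derivation
# ---------------------------------------------------------------------------

def _stable_hash(s: str) -> int:
    return int.from_bytes(hashlib.sha256(s.encode("utf-8")).digest()[:8], "big")


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Random generator for one subject, stable under cohort-size changes."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _stable_hash(subject_id)]))


def _panel_rng(panel_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(panel_seed), _PANEL_STREAM_KEY]))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def draw_gene_panel(config: CohortConfig, rng: Optional[np.random.Generator] = None) -> GenePanel:
    """Draw per-gene cosinor parameters (mesor, amplitude, acrophase) once per cohort."""
    rng = _panel_rng(config.panel_seed) if rng is None else rng
    n = int(config.n_genes)
    mesor = rng.normal(config.gene_mesor_mean, config.gene_mesor_sd, n)
    amplitude = np.abs(rng.normal(config.gene_amplitude_mean, config.gene_amplitude_sd, n))
    acrophase = rng.uniform(0.0, 24.0, n)
    gene_ids = [f"G{i+1:04d}" for i in range(n)]
    return GenePanel(gene_ids, mesor, amplitude, acrophase)


def simulate_expression(subject: SubjectProfile, times, config: CohortConfig,
                        panel: GenePanel,
                        rng: Optional[np.random.Generator] = None) -> list:
    """Expression samples for one subject at the given clock times.

    A subject advanced by delta hours expresses each gene as if the wall clock
    read t + delta, i.e. the per-gene peak moves to phi_g - delta.
    """
    rng = subject_rng(config.seed, subject.subject_id) if rng is None else rng
    delta = subject.phase_offset_delta
    out = []
    for t in times:
        t = float(t) % 24.0
        phase = 2.0 * np.pi * (t - (panel.acrophase - delta)) / 24.0
        vals = panel.mesor + panel.amplitude * np.cos(phase)
        if config.gene_noise_sd > 0:
            vals = vals + rng.normal(0.0, config.gene_noise_sd, len(panel.gene_ids))
        session = "AM" if 4.0 <= t < 16.0 else "PM"
        out.append(ExpressionSample(subject.subject_id, t, session, vals))
    return out


def true_dlmo(subject: SubjectProfile, config: CohortConfig) -> float:
    """Ground-truth melatonin onset for a subject, session-relative hours."""
    return config.dlmo_base - subject.phase_offset_delta


def simulate_melatonin(subject: SubjectProfile, sampling_times, config: CohortConfig,
                       rng: Optional[np.random.Generator] = None):
    """Evening saliva and plasma melatonin series (the "hockey stick").

    Plasma is flat at baseline until the subject's onset, then rises linearly;
    saliva is a fixed fraction of plasma plus assay noise, truncated at zero.
    Times are session-relative (monotone; 24.5 means 00:30 the next morning).
    """
    rng = subject_rng(config.seed, subject.subject_id) if rng is None else rng
    t = np.asarray(sampling_times, dtype=float)
    onset = true_dlmo(subject, config)
    plasma = config.melatonin_baseline + config.melatonin_rise_rate * np.maximum(0.0, t - onset)
    plasma_obs = plasma
    if config.plasma_noise_sd > 0:
        plasma_obs = np.maximum(0.0, plasma + rng.normal(0.0, config.plasma_noise_sd, t.size))
    saliva = config.saliva_plasma_ratio_true * plasma
    if config.saliva_noise_sd > 0:
        saliva = np.maximum(0.0, saliva + rng.normal(0.0, config.saliva_noise_sd, t.size))
    return (MelatoninProfile(subject.subject_id, "saliva", t, saliva),
            MelatoninProfile(subject.subject_id, "plasma", t, plasma_obs))


def simulate_activity(subject: SubjectProfile, config: CohortConfig,
                      rng: Optional[np.random.Generator] = None) -> ActivitySeries:
    """Multi-day epoch-level activity counts with a diary-style rest schedule.

    Counts follow a square wave (day level while awake, night level during the
    rest interval, the whole schedule shifted earlier by the subject's phase
    offset), with additive noise and, at fragmentation > 0, brief random
    intrusions during which the wake/rest level is swapped.
    """
    rng = subject_rng(config.seed, subject.subject_id) if rng is None else rng
    delta = subject.phase_offset_delta
    epoch_h = config.epoch_minutes / 60.0
    # recording runs noon-to-noon so every night's rest interval lies wholly
    # inside the span (no delta-dependent edge truncation)
    start_h = 12.0
    span_end = start_h + config.n_days * 24.0
    n_epochs = int(round(config.n_days * 24.0 / epoch_h))
    starts = start_h + np.arange(n_epochs) * epoch_h
    centers = starts + epoch_h / 2.0

    rest_intervals = []
    for d in range(config.n_days):
        jit_b = rng.normal(0.0, config.sleep_time_jitter_sd) if config.sleep_time_jitter_sd > 0 else 0.0
        jit_w = rng.normal(0.0, config.sleep_time_jitter_sd) if config.sleep_time_jitter_sd > 0 else 0.0
        bed = d * 24.0 + config.bedtime_base - delta + jit_b
        wake = (d + 1) * 24.0 + config.waketime_base - delta + jit_w
        bed = max(bed, start_h)
        wake = min(wake, span_end)
        if wake > bed:
            rest_intervals.append((bed, wake))

    in_rest = np.zeros(n_epochs, dtype=bool)
    for bed, wake in rest_intervals:
        in_rest |= (centers >= bed) & (centers < wake)

    level = np.where(in_rest, config.activity_night_level, config.activity_day_level)

    if config.fragmentation > 0 and config.intrusion_rate_per_minute > 0:
        p = config.fragmentation * config.intrusion_rate_per_minute * config.epoch_minutes
        starts_idx = np.nonzero(rng.random(n_epochs) < min(p, 1.0))[0]
        swapped = np.zeros(n_epochs, dtype=bool)
        mean_epochs = max(config.intrusion_mean_minutes / config.epoch_minutes, 1.0)
        for i in starts_idx:
            dur = int(rng.geometric(1.0 / mean_epochs))
            swapped[i:i + dur] = True
        level = np.where(swapped ^ in_rest, config.activity_night_level,
                         config.activity_day_level)

    counts = level.astype(float)
    if config.activity_noise_sd > 0:
        ref = max(config.activity_day_level, 1.0)
        scale = config.activity_noise_sd * np.sqrt(np.maximum(level, 1.0) / ref)
        counts = np.maximum(0.0, counts + rng.normal(0.0, 1.0, n_epochs) * scale)

    return ActivitySeries(subject.subject_id, starts, int(config.epoch_minutes),
                          counts, rest_intervals)


def classify_meq(score: int) -> str:
    """Map an MEQ total score to a chronotype band.

    Morning >= 59, evening <= 41, intermediate otherwise (Horne-Ostberg bands;
    the two boundary scores are assigned to the outer categories).
    """
    if score >= MORNING_CUTOFF:
        return "morning"
    if score <= EVENING_CUTOFF:
        return "evening"
    return "intermediate"


def assign_meq(subject: SubjectProfile, config: CohortConfig,
               rng: Optional[np.random.Generator] = None):
    """MEQ total score and chronotype label from the latent phase offset."""
    rng = subject_rng(config.seed, subject.subject_id) if rng is None else rng
    noise = rng.normal(0.0, config.meq_noise_sd) if config.meq_noise_sd > 0 else 0.0
    raw = config.meq_intercept + config.meq_slope * subject.phase_offset_delta + noise
    score = int(np.clip(round(raw), MEQ_MIN, MEQ_MAX))
    return score, classify_meq(score)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full multimodal cohort.

    Deterministic given (config, seed): the same configuration always yields a
    bit-identical cohort, and each subject's data depends only on the seed and
    the subject's own identifier.
    """
    config.validate()
    panel = draw_gene_panel(config)
    weights = np.array([config.chronotype_weights[c] for c in _CHRONOTYPES], float)
    weights = weights / weights.sum()

    mel_times = np.arange(config.melatonin_sampling_start,
                          config.melatonin_sampling_end + 1e-9,
                          config.melatonin_sampling_interval)

    subjects = []
    for i in range(int(config.n_subjects)):
        sid = f"S{i+1:03d}"
        rng = subject_rng(config.seed, sid)
        stratum = _CHRONOTYPES[rng.choice(len(_CHRONOTYPES), p=weights)]
        delta = rng.normal(config.phase_offset_mean_by_type[stratum],
                           config.phase_offset_sd)
        age = float(rng.normal(config.age_mean, config.age_sd))
        sex = int(rng.random() < config.female_fraction)
        subj = SubjectProfile(sid, age, sex, float(delta), 0, "")
        subj.meq_score, subj.chronotype_label = assign_meq(subj, config, rng)

        jitter = (rng.normal(0.0, config.sample_time_jitter_sd, 2)
                  if config.sample_time_jitter_sd > 0 else np.zeros(2))
        if config.sample_times_mode == "uniform":
            # antipodal pairs: with two-sample centering the pair's feature
            # vectors are exact negatives, which matches the geometry of
            # antipodal times; ~12 h is also the most informative spacing
            t1 = rng.uniform(0.0, 24.0)
            pm_t = (t1 + jitter[0]) % 24.0
            am_t = (t1 + 12.0 + jitter[1]) % 24.0
            subj.expression_samples = simulate_expression(subj, [pm_t, am_t],
                                                          config, panel, rng)
            subj.expression_samples[0].session = "T1"
            subj.expression_samples[1].session = "T2"
        else:
            pm_t = (config.pm_sample_time + jitter[0]) % 24.0
            am_t = (config.am_sample_time + jitter[1]) % 24.0
            subj.expression_samples = simulate_expression(subj, [pm_t, am_t],
                                                          config, panel, rng)
            subj.expression_samples[0].session = "PM"
            subj.expression_samples[1].session = "AM"

        subj.melatonin_saliva, subj.melatonin_plasma = simulate_melatonin(
            subj, mel_times, config, rng)
        subj.true_dlmo = true_dlmo(subj, config)
        subj.activity = simulate_activity(subj, config, rng)
        subjects.append(subj)

    return Cohort(config, panel, subjects)
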