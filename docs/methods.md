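# Methods

## Overview

`circphen` validates blood-transcriptomic circadian phenotyping on simulated
multimodal cohorts. A single latent per-subject quantity — the phase offset
δ (hours; positive = internal clock ahead of local time) — drives every
simulated modality, so agreement analyses can be checked against ground
truth. The pipeline: simulate a cohort; train a transcriptomic clock on an
independently seeded reference cohort; predict circadian time for each blood
sample; derive the transcriptomic angle and its tolerance-accuracy curve;
compute DLMO, rest–activity metrics and MEQ chronotype; and quantify
cross-method agreement.

## The cohort generator

Each subject is assigned a chronotype stratum (default weights 0.7 morning /
0.3 intermediate, emulating a morning-leaning older-adult cohort), then
δ ~ N(stratum mean, `phase_offset_sd`), with stratum means +2.7 / 0 / −2.7 h
and SD 1.0 h by default. These values place the simulated strata near the
reference cohort's printed characteristics (MEQ ≈ 70 morning / 52
intermediate, angle difference ≈ 2–3 h between strata).

**Expression.** A panel of `n_genes` = 40 genes carries cosinor parameters
(mesor ~ N(7, 1), amplitude ~ |N(2, 0.4)|, acrophase ~ U[0, 24)) drawn from
a dedicated `panel_seed`, deliberately independent of the cohort seed: gene
rhythms are biology shared by every cohort, which is what lets a clock
trained on one cohort transfer to another. Samples follow
`x_g(t) = m_g + A_g cos(2π(t − (φ_g − δ))/24) + N(0, gene_noise_sd²)` with
noise SD 1.0, i.e. a 2:1 amplitude:noise ratio. The study protocol
("visit" mode) draws at ~20:00 and ~10:00 (jitter SD 0.5 h); "uniform" mode
draws antipodal pairs at a uniform time of day (see *Training design*).

**Melatonin.** Plasma is flat at `melatonin_baseline` (2 pg/mL) until the
subject's onset `dlmo_base − δ` (base 20.6 h), then rises linearly at
8 pg/mL/h; saliva is `saliva_plasma_ratio_true` (0.3) times plasma plus
truncated N(0, 0.5²) assay noise. The piecewise-linear rise gives DLMO
recovery a closed form: with threshold `baseline + k`, the onset estimate is
exactly `(dlmo_base − δ) + k/rise_rate`. Evening times are session-relative
monotone hours (24.5 = 00:30), so interpolation never spans a clock wrap.

**Actigraphy.** Counts form a square wave — 300/epoch awake, 10 during the
rest interval (bed 22.75 − δ, wake 7.08 − δ, per-night jitter SD 0.25 h) —
plus additive noise (SD 50 at the wake level, scaled by √level) and, at
`fragmentation` > 0, brief intrusions (rate `fragmentation` × 0.02/min,
geometric length, mean 10 min) during which the wake/rest level is swapped.
The recording runs noon-to-noon so every night lies wholly inside the span;
without this, δ-dependent edge truncation induces spurious
amplitude/IS–angle correlations.

**MEQ.** Score = round(53 + 6δ + N(0, 3²)) clipped to [16, 86]; bands
morning ≥ 59, evening ≤ 41 (the two boundary scores go to the outer
categories per the original instrument bands).

**Reproducibility.** Each subject's stream derives from
(cohort seed, sha256(subject_id)), so enlarging a cohort never perturbs
subjects already generated; identical configs are bit-identical.

## The clock

Within-subject normalization centers each gene on the subject's own mean
across that subject's samples; with two samples the pair's feature vectors
are exact negatives. Two ridge regressions (shared penalty) map normalized
expression to cos and sin of sampling time; predicted time is
`atan2(ŝ, ĉ)·24/2π mod 24`. The penalty is chosen by leave-one-subject-out
search over {10⁻², 10⁻¹, 1, 10} minimizing mean absolute angular error
(typically selecting 10 under default noise).

**Training design.** Two properties of the two-sample protocol shape the
training cohort:

1. *Time spread.* If every training draw sits at the same two clock times,
   sampling-time variance (jitter, SD 0.5 h) is small next to phase-offset
   variance (SD 1.5 h), and least squares regresses predictions toward the
   mean draw time — attenuating precisely the phase signal of interest.
   Training samples are therefore distributed uniformly around the clock
   face, the round-the-clock time-course design transcriptomic clocks are
   actually trained on.
2. *Pair spacing.* Because the two centered feature vectors are exact
   negatives, a single linear model can represent the pair's two target
   times exactly only when they are antipodal; training pairs are spaced
   12 h. The application protocol's 14 h spacing (20:00 → 10:00) leaves a
   small irreducible systematic error that is simply part of the realistic
   conditions.
3. *Reference population.* The training cohort has zero-mean phase offsets.
   Training on the phase-advanced study mix would absorb the cohort's mean
   advance into the intercepts, silently re-zeroing the mean transcriptomic
   angle — the angle is only interpretable against a calibration population
   that is not itself shifted.

**Angles and accuracy.** The signed angle is
`((predicted − true + 12) mod 24) − 12` ∈ [−12, 12), antipodal errors
reporting −12; AM and PM angles are averaged arithmetically (safe while
angles are far from ±12; pathological antipodal inputs would need circular
averaging). The tolerance-accuracy curve is the fraction of samples with
|angle| ≤ h for h ∈ [0, 12]; `nauc` is its exact area over 12, computed in
closed form as `1 − mean|angle|/12` rather than by quadrature on a grid —
the empirical curve is a step function, and gridded trapezoids add a
half-step bias at every jump (the gridded curve is still exported for
plotting, default 0.1 h resolution).

## DLMO

The saliva threshold is `10 pg/mL × mean(saliva_i/plasma_i)` over paired
draws (mean of per-pair ratios, not ratio of means); the pipeline pairs each
subject's saliva sample nearest 20:00 with the concurrent plasma value.
Profile QC encodes the hockey-stick requirement deterministically: at least
one strictly sub-threshold sample before the rise, ≥ 2 consecutive
at/above-threshold samples, and no return below threshold afterwards; with
multiple up-crossings the sustained (final) crossing defines onset and
earlier transients are ignored. Onset is the linear interpolation between
the last sub-threshold and first at/above-threshold samples. Reason codes:
`insufficient_samples` (< 4), `no_crossing`, `onset_before_sampling`,
`unsustained_crossing`.

## Actigraphy metrics

M10/L5 are the extreme contiguous 10 h/5 h windows of the clock-time-binned
average 24 h profile (30-min bins by default; circular, wrapping midnight;
ties resolve to the earliest start). Amplitude = M10 mean − L5 mean,
unnormalized (count scale); relative amplitude is exported but unused. IS
and IV use the standard nonparametric definitions on 60-min bins:

```
IS = n Σ_h (x̄_h − x̄)² / (p Σ_i (x_i − x̄)²)        ∈ [0, 1]
IV = n Σ_{i≥2} (x_i − x_{i−1})² / ((n−1) Σ_i (x_i − x̄)²)   ≥ 0
```

Constant series raise a degenerate-input error (zero variance). Days with
< 80% epoch coverage are excluded from the average profile. Sleep scoring is
diary-anchored: within a rest interval an epoch is asleep when counts <
`wake_threshold` (40/epoch); TST, WASO (awake minutes after first sleep) and
efficiency follow per night; bedtime/waketime come from the diary verbatim;
clock-time summaries are circular means.

## Agreement statistics

Partial correlation residualizes both variables on [1, covariates] by least
squares and tests the residual Pearson r against t with n − 2 − k df; k = 0
reduces exactly to plain Pearson. Bland–Altman converts both series to
z-scores (after negating clock-time phase measures — DLMO, bedtime,
waketime, midsleep, M10 — so everything points "positive = advanced"); the
mean z-difference is identically zero for complete cases, so the informative
output is the 1.96 SD limits of agreement, whose half-width is analytically
`1.96·√(2 − 2r)`. Group comparisons use equal-variance Student's t
(continuous) and chi-squared without continuity correction (categorical);
normality uses one-sample KS against a fitted normal, flagged with the
Lilliefors caveat. Complete-case analysis throughout; no multiple-testing
correction. For linear statistics, clock times are first unwrapped onto a
continuous scale centered on the cohort circular mean, so times straddling
midnight do not fold.

## Problem sizes and numerical choices

Default runs use 40 subjects (the study scale); sign-pattern and coherence
checks use 200; the AM–PM consistency simulation uses 2000; closed-form
Monte-Carlo checks use 10⁵ draws or 100 seeds. These sizes make every result
statistically stable while each analysis completes in seconds. Ties in
window scans resolve to the earliest clock start; the antipodal angle maps
to −12; ridge with penalty 0 on a rank-deficient design raises rather than
silently pseudo-inverting.

## What the simulation does and does not show

The generator reproduces the *structure* the analyses assume — cosinor gene
rhythms with a shared latent offset, hockey-stick melatonin, square-wave
rest–activity — not the messiness of real data: no ultradian activity
structure, no melatonin suppression by light, no assay batch effects, no
missing epochs, no age-dependent amplitude loss. Passing tests therefore
demonstrate that the estimators are correct and coherent under their own
model (including realistic noise levels), not that the clock would achieve
the same accuracy on real RNA-seq; the synthetic IS (~0.95) is accordingly
higher and IV (~0.3) lower than typical field values, since real days repeat
far less perfectly. Accuracy numbers on synthetic data should be read as
upper bounds under clean model match.
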