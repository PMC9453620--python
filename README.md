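# circphen — blood-transcriptomic circadian phenotyping

Circadian phase — the timing of a person's internal ~24 h clock relative to
local time — is hard to measure. Dim-light melatonin onset (DLMO), the gold
standard, needs an evening of controlled dim-light sampling; wrist actigraphy
is confounded by behavior; questionnaires are subjective. Transcriptomic
clocks instead predict internal time from the expression of rhythmic genes in
whole blood, needing only two suitably spaced draws. `circphen` implements
and validates this idea end to end on simulated multimodal cohorts of older
adults: it predicts circadian time from two-timepoint blood expression,
derives the **transcriptomic angle** (how far the internal clock runs ahead
of the wall clock), and quantifies agreement with DLMO, rest–activity
rhythms, and questionnaire chronotype — against known simulation ground
truth.

## The model

Each gene follows a cosinor in internal time; a subject whose phase is
advanced by δ hours expresses gene *g* as

```
x_g(t) = m_g + A_g · cos(2π (t − (φ_g − δ)) / 24) + ε,   ε ~ N(0, σ²)
```

The same latent δ drives every modality: melatonin onset at `dlmo_base − δ`
(baseline then linear "hockey-stick" rise), a rest interval shifted earlier
by δ, and an MEQ score `53 + 6δ + noise` (morning ≥ 59, evening ≤ 41).

The clock itself is TimeSignature-style: within-subject normalization (each
gene centered on the subject's own mean across their samples) followed by two
ridge regressions of `cos(2πt/24)` and `sin(2πt/24)` on normalized
expression; predicted time is `atan2(ŝ, ĉ)·24/2π`. The signed circular
difference between predicted and true sampling time, averaged over a
subject's AM and PM samples, is the transcriptomic angle (positive =
advanced). Sweeping an error tolerance h over [0, 12] h gives the
tolerance-accuracy curve; its normalized area (nAUC, computed exactly as
`1 − mean|angle|/12`) summarizes accuracy. DLMO is found by linear
interpolation at a saliva threshold calibrated to 10 pg/mL plasma
equivalent; actigraphy yields M10/L5, amplitude, interdaily stability and
intradaily variability (Van Someren nonparametric definitions); agreement
uses Pearson and age/sex-adjusted partial correlations plus z-scored
Bland–Altman limits of agreement.

## Worked example

Run the numbered analyses (each regenerates its inputs deterministically and
writes tables under `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_train_clock.py
python analysis/03_clock_accuracy.py
python analysis/04_phase_markers.py
python analysis/05_agreement.py
python analysis/06_summary_table.py
```

which prints, among other things:

```
simulated 40 subjects (seed 42) -> results/cohort
chronotype mix: {'morning': 28, 'intermediate': 10, 'evening': 2}
...
transcriptomic angle: 1.93 +/- 1.93 h
tolerance-accuracy nAUC: 0.795
AM-PM internal consistency r = 0.924
...
DLMO profiles passing hockey-stick QC: 36/40
mean M10 start 7.54 h, amplitude 277 counts, IS 0.95, IV 0.32
...
  waketime                 r = -0.949  p = 0.0000 *
  m10_start                r = -0.827  p = 0.0000 *
  bedtime                  r = -0.951  p = 0.0000 *
  dlmo_time                r = -0.941  p = 0.0000 *
  meq_score                r = +0.908  p = 0.0000 *
  intradaily_variability   r = +0.234  p = 0.1572
```

Read: the 40-subject morning-leaning cohort has a mean angle of ~+2 h (its
internal clocks run ahead of local time); the clock places 80 held-out blood
samples with nAUC ≈ 0.8; and the angle agrees with every independent phase
marker — earlier waketime, bedtime, M10 and DLMO, higher MEQ — while sleep
quantity/quality and rhythm fragmentation are uncorrelated, the dissociation
a phase biomarker should show (at n = 40 a couple of non-phase measures graze
p < 0.05; at n = 200 they do not).

The same stages are available as a CLI on CSV/TSV files
(`circphen simulate|train|predict|accuracy|dlmo|actigraphy|agree|summarize|run`),
e.g. `circphen run --seed 17 --out runs/r1/`.

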