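"""End-to-end orchestration: simulate, train, phenotype, and validate.

`run_validation` composes the whole study workflow on synthetic data:

1. generate a test cohort and an independently seeded training cohort;
2. train the transcriptomic clock on the training cohort and predict both
   samples of every test subject, yielding per-subject transcriptomic angles
   and the cohort tolerance-accuracy curve (nAUC);
3. calibrate the saliva melatonin threshold from the evening paired
   saliva/plasma draw, QC each profile, and interpolate DLMO;
4. compute rest-activity rhythm metrics and diary-anchored sleep variables;
5. merge everything into a per-subject phenotype table, build the
   chronotype-stratified summary, and run the agreement statistics
   (Pearson/partial correlations, z-scored Bland-Altman).

Runs are deterministic given (config, seed); a JSON manifest records the
configuration hash, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import actigraphy_metrics as am
from . import agreement_stats as ag
from . import melatonin_dlmo as md
from . import synthetic_cohort as sc
from . import transcriptomic_clock as tc
from .circular import circular_mean_hours, circular_sd_hours, unwrap_hours

log = logging.getLogger("circphen.pipeline")

TRAIN_SEED_OFFSET = 10_000_019  # derives the training-cohort seed from the run seed

# phenotype variables: (column, kind) where kind governs summary statistics
SUMMARY_VARIABLES = [
    ("age", "continuous"),
    ("sex", "categorical"),
    ("dlmo_time", "clock"),
    ("meq_score", "continuous"),
    ("transcriptomic_angle", "continuous"),
    ("m10_start", "clock"),
    ("amplitude", "continuous"),
    ("interdaily_stability", "continuous"),
    ("intradaily_variability", "continuous"),
    ("bedtime", "clock"),
    ("midsleep", "clock"),
    ("waketime", "clock"),
    ("total_sleep_time", "continuous"),
    ("sleep_efficiency", "continuous"),
    ("waso", "continuous"),
]

# phase measures where later clock time = delayed phase: negated before
# z-scoring in Bland-Altman so they share the angle's positive = advanced
# direction. MEQ already points that way.
NEGATE_FOR_AGREEMENT = {"dlmo_time", "bedtime", "waketime", "midsleep", "m10_start"}

AGREEMENT_VARIABLES = ["waketime", "m10_start", "bedtime", "amplitude",
                       "dlmo_time", "meq_score", "midsleep",
                       "interdaily_stability", "intradaily_variability",
                       "total_sleep_time", "sleep_efficiency", "waso"]


def derive_train_seed(seed: int) -> int:
    return int((int(seed) + TRAIN_SEED_OFFSET) % (2 ** 31))


def training_config(config, seed=None):
    """The reference-population configuration the clock is trained on.

    Two changes relative to the study cohort: sampling times are distributed
    uniformly around the clock (round-the-clock time-course design), and the
    latent phase offsets are zero-mean — the clock's calibration should come
    from a general reference population, not from the phase-advanced cohort
    it is later applied to (otherwise the cohort's mean advance is silently
    absorbed into the intercept and the mean transcriptomic angle reads 0).
    """
    seed = derive_train_seed(config.seed) if seed is None else int(seed)
    return dataclasses.replace(
        config, seed=seed, sample_times_mode="uniform",
        phase_offset_mean_by_type={"morning": 0.0, "intermediate": 0.0,
                                   "evening": 0.0})


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def cohort_expression_by_subject(cohort) -> dict:
    by_subject = {}
    for s in cohort.subjects:
        for sample in s.expression_samples:
            sample.gene_ids = cohort.gene_panel.gene_ids
        by_subject[s.subject_id] = list(s.expression_samples)
    return by_subject


def train_clock_on_cohort(cohort, ridge_penalty=1.0) -> tc.ClockModel:
    normalized = tc.within_subject_normalize(cohort_expression_by_subject(cohort))
    return tc.train_clock(normalized, ridge_penalty=ridge_penalty,
                          seed=cohort.config.seed)


def predict_angles(model: tc.ClockModel, samples_by_subject: dict) -> pd.DataFrame:
    """Per-sample transcriptomic times/angles and per-subject mean angle."""
    normalized = tc.within_subject_normalize(samples_by_subject)
    singles = tc.single_sample_subjects(samples_by_subject)
    rows = []
    for sid, pairs in normalized.items():
        if sid in singles:
            log.warning("subject %s has a single sample; prediction unreliable", sid)
        by_session = {"subject_id": sid}
        for sample, vals in pairs:
            pred = tc.predict_time(model, vals,
                                   getattr(sample, "gene_ids", None))
            ang = tc.signed_angle(pred, sample.clock_time)
            by_session[sample.session] = ang
            rows.append({"subject_id": sid, "session": sample.session,
                         "clock_time": sample.clock_time,
                         "transcriptomic_time": pred, "angle": ang})
        pheno = tc.subject_angle(by_session)
        for r in rows:
            if r["subject_id"] == sid:
                r["angle_mean"] = pheno.angle_mean
    return pd.DataFrame(rows)


def melatonin_phenotypes(cohort, plasma_equivalent=md.PLASMA_EQUIVALENT_DEFAULT,
                         pairing_time: float = 20.0) -> pd.DataFrame:
    """Calibrated threshold + per-subject DLMO for a cohort.

    The calibration pairs each subject's saliva sample nearest the evening
    blood draw (~20:00) with the concurrent plasma value, mirroring a design
    where plasma is only available at venipuncture times.
    """
    pairs = []
    for s in cohort.subjects:
        sal, pla = s.melatonin_saliva, s.melatonin_plasma
        i = int(np.argmin(np.abs(np.asarray(sal.times) - pairing_time)))
        if pla.concentrations[i] > 0:
            pairs.append((sal.concentrations[i], pla.concentrations[i]))
    threshold = md.calibrate_threshold(pairs, plasma_equivalent)
    rows = []
    for s in cohort.subjects:
        res = md.dlmo_for_profile(s.melatonin_saliva, threshold)
        rows.append({"subject_id": s.subject_id, "threshold": res.threshold,
                     "dlmo_time": res.dlmo_time, "qc_pass": res.qc_pass,
                     "qc_reason": res.qc_reason})
    return pd.DataFrame(rows)


def actigraphy_phenotypes(cohort, wake_threshold=am.WAKE_THRESHOLD_DEFAULT) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        rm = am.rhythm_metrics(s.activity)
        ss = am.sleep_summary(s.activity, wake_threshold=wake_threshold)
        rows.append({
            "subject_id": s.subject_id,
            "m10_start": rm.m10_start, "m10_mean": rm.m10_mean,
            "l5_start": rm.l5_start, "l5_mean": rm.l5_mean,
            "amplitude": rm.amplitude,
            "interdaily_stability": rm.interdaily_stability,
            "intradaily_variability": rm.intradaily_variability,
            "bedtime": ss.bedtime, "waketime": ss.waketime,
            "midsleep": ss.midsleep, "total_sleep_time": ss.total_sleep_time,
            "sleep_efficiency": ss.sleep_efficiency, "waso": ss.waso,
        })
    return pd.DataFrame(rows)


def build_phenotype_table(cohort, angles: pd.DataFrame, dlmo: pd.DataFrame,
                          acti: pd.DataFrame) -> pd.DataFrame:
    """One row per subject, clock times unwrapped onto a continuous scale."""
    subj = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
        "meq_score": s.meq_score, "chronotype_label": s.chronotype_label,
        "true_phase_offset": s.phase_offset_delta,
    } for s in cohort.subjects])
    ang = (angles.groupby("subject_id")["angle_mean"].first()
           .rename("transcriptomic_angle").reset_index())
    table = (subj.merge(ang, on="subject_id", how="left")
                 .merge(dlmo[["subject_id", "dlmo_time", "qc_pass"]],
                        on="subject_id", how="left")
                 .merge(acti, on="subject_id", how="left"))
    for col in ("bedtime", "waketime", "midsleep", "m10_start"):
        vals = table[col].to_numpy(float)
        finite = np.isfinite(vals)
        if finite.any():
            center = circular_mean_hours(vals[finite])
            table[col] = unwrap_hours(vals, center)
    return table


# ---------------------------------------------------------------------------
# summaries and agreement
# ---------------------------------------------------------------------------

def _fmt_stats(values, kind):
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan
    if kind == "clock":
        return circular_mean_hours(v), circular_sd_hours(v) * 60.0  # hours, minutes
    if kind == "categorical":
        return float(v.sum()), 100.0 * float(v.mean())  # count, percent
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def build_phenotype_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Chronotype-stratified summary: mean +/- SD per stratum, difference flags.

    Clock-time variables are summarized as circular mean (hours) with circular
    SD in minutes; categorical ones as count and percent. When exactly two
    strata are present the between-stratum comparison (Student's t or
    chi-squared) is reported with a significance flag at ``alpha``.
    """
    strata = [c for c in ("morning", "intermediate", "evening")
              if (table["chronotype_label"] == c).any()]
    if len(strata) < 2:
        log.warning("only %d chronotype stratum present; stratified comparisons skipped",
                    len(strata))
    rows = []
    compare = strata[:2] if len(strata) >= 2 else None
    for col, kind in SUMMARY_VARIABLES:
        if col not in table.columns:
            continue
        mean, spread = _fmt_stats(table[col], kind)
        row = {"variable": col, "kind": kind, "overall_mean": mean,
               "overall_spread": spread, "n_total": int(table[col].notna().sum())}
        for stratum in strata:
            sub = table.loc[table["chronotype_label"] == stratum, col]
            m, s = _fmt_stats(sub, kind)
            row[f"{stratum}_mean"], row[f"{stratum}_spread"] = m, s
            row[f"{stratum}_n"] = int(sub.notna().sum())
        if compare is not None:
            sub = table[table["chronotype_label"].isin(compare)]
            vals = sub[col].to_numpy()
            grp = sub["chronotype_label"].to_numpy()
            try:
                gk = "categorical" if kind == "categorical" else "continuous"
                stat, p, test = ag.group_compare(vals[pd.notna(vals)],
                                                 grp[pd.notna(vals)], kind=gk)
                row.update(statistic=stat, p_value=p, test=test,
                           significant=bool(p < alpha))
            except (ValueError, ag.DegenerateInputError):
                row.update(statistic=np.nan, p_value=np.nan, test="none",
                           significant=False)
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_analyses(table: pd.DataFrame,
                       covariates=("age", "sex")) -> tuple:
    """Correlations and Bland-Altman agreement of the angle with each phenotype."""
    corr_rows, ba_rows = [], []
    x = table["transcriptomic_angle"].to_numpy(float)
    covs = [table[c].to_numpy(float) for c in covariates]
    for col in AGREEMENT_VARIABLES:
        if col not in table.columns:
            continue
        y = table[col].to_numpy(float)
        try:
            plain = ag.pearson_correlation(x, y, labels=("transcriptomic_angle", col))
            partial = ag.partial_correlation(x, y, covs,
                                             labels=("transcriptomic_angle", col),
                                             covariate_labels=tuple(covariates))
        except (ValueError, ag.DegenerateInputError) as exc:
            log.warning("correlation with %s skipped: %s", col, exc)
            continue
        corr_rows.append({"variable": col, "r": plain.r, "p": plain.p_value,
                          "n": plain.n, "partial_r": partial.r,
                          "partial_p": partial.p_value,
                          "covariates": "+".join(covariates)})
        orientation = -1 if col in NEGATE_FOR_AGREEMENT else 1
        try:
            ba = ag.bland_altman(x, y, orientation=orientation)
        except (ValueError, ag.DegenerateInputError):
            continue
        ba_rows.append({"variable": col, "orientation": orientation,
                        "mean_difference": ba.mean_difference,
                        "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper})
    return pd.DataFrame(corr_rows), pd.DataFrame(ba_rows)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_validation(config=None, seed=None, out_dir=None,
                   ridge_penalty="auto") -> dict:
    """Execute the whole validation workflow; optionally write a run directory.

    Returns a dict with the phenotype table, stratified summary, accuracy
    curve, per-sample angles, DLMO results, correlation/agreement tables,
    the trained model, and the run manifest.
    """
    config = sc.default_config() if config is None else config
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()

    train_cfg = training_config(config)
    log.info("generating training cohort (seed %d) and test cohort (seed %d)",
             train_cfg.seed, config.seed)
    train_cohort = sc.generate_cohort(train_cfg)
    test_cohort = sc.generate_cohort(config)

    model = train_clock_on_cohort(train_cohort, ridge_penalty=ridge_penalty)
    angles = predict_angles(model, cohort_expression_by_subject(test_cohort))
    if len(angles):
        curve = tc.accuracy_curve(angles["angle"].to_numpy(float))
        curve_df = pd.DataFrame({"tolerance_h": curve.tolerances,
                                 "fraction_correct": curve.fraction_correct})
        nauc = curve.nauc
    else:
        curve_df, nauc = pd.DataFrame(), float("nan")

    dlmo = melatonin_phenotypes(test_cohort)
    acti = actigraphy_phenotypes(test_cohort)
    table = build_phenotype_table(test_cohort, angles, dlmo, acti)
    summary = build_phenotype_summary(table)
    correlations, bland = agreement_analyses(table)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "circphen", "version": __version__,
        "seed": int(config.seed), "train_seed": int(train_cfg.seed),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": len(test_cohort), "nauc": nauc,
        "ridge_penalty": model.ridge_penalty,
    }

    out = {"phenotypes": table, "summary": summary, "angles": angles,
           "accuracy_curve": curve_df, "nauc": nauc, "dlmo": dlmo,
           "actigraphy": acti, "correlations": correlations,
           "bland_altman": bland, "model": model, "manifest": manifest}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("phenotypes", "summary", "angles", "accuracy_curve",
                     "dlmo", "actigraphy", "correlations", "bland_altman"):
            out[name].to_csv(out_dir / f"{name}.csv", index=False)
        model.to_json(out_dir / "clock_model.json")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        log.info("run written to %s (nAUC %.3f)", out_dir, nauc)
    return out
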