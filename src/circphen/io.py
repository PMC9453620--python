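"""Plain-text readers and writers for every modality.

Formats
-------
expression    TSV matrix, rows = genes, columns = sample IDs, plus a sidecar
              sample-metadata CSV (sample_id, subject_id, clock_time, session)
melatonin     long CSV: subject_id, medium, time, pg_ml (session-relative hours)
activity      epoch CSV: subject_id, timestamp (ISO-8601), counts; rest-interval
              CSV: subject_id, date, bedtime, waketime (HH:MM)
subjects      CSV: subject_id, age, sex, phase_offset_delta, meq_score,
              chronotype_label
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import ActivitySeries, ExpressionSample, MelatoninProfile

_BASE_DATE = _dt.datetime(2000, 1, 3)  # arbitrary Monday anchoring hour 0


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def write_subjects(cohort, path) -> None:
    rows = [{"subject_id": s.subject_id, "age": s.age, "sex": s.sex,
             "phase_offset_delta": s.phase_offset_delta,
             "meq_score": s.meq_score, "chronotype_label": s.chronotype_label}
            for s in cohort.subjects]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression(cohort, matrix_path, meta_path) -> None:
    cols, meta = {}, []
    for s in cohort.subjects:
        for sample in s.expression_samples:
            sample_id = f"{s.subject_id}_{sample.session}"
            cols[sample_id] = sample.values
            meta.append({"sample_id": sample_id, "subject_id": s.subject_id,
                         "clock_time": sample.clock_time, "session": sample.session})
    mat = pd.DataFrame(cols, index=cohort.gene_panel.gene_ids)
    mat.index.name = "gene_id"
    mat.to_csv(matrix_path, sep="\t")
    pd.DataFrame(meta).to_csv(meta_path, index=False)


def read_expression(matrix_path, meta_path) -> dict:
    """Read an expression matrix + metadata into samples grouped by subject.

    Returns subject_id -> list of ExpressionSample; each sample additionally
    carries the gene identifiers it was read with (``gene_ids`` attribute).
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path)
    gene_ids = list(mat.index)
    by_subject: dict = {}
    for row in meta.itertuples(index=False):
        if row.sample_id not in mat.columns:
            raise KeyError(f"sample {row.sample_id!r} absent from expression matrix")
        sample = ExpressionSample(row.subject_id, float(row.clock_time) % 24.0,
                                  str(row.session),
                                  mat[row.sample_id].to_numpy(dtype=float))
        sample.gene_ids = gene_ids
        by_subject.setdefault(row.subject_id, []).append(sample)
    return by_subject


# ---------------------------------------------------------------------------
# melatonin
# ---------------------------------------------------------------------------

def write_melatonin(cohort, path) -> None:
    rows = []
    for s in cohort.subjects:
        for prof in (s.melatonin_saliva, s.melatonin_plasma):
            for t, c in zip(prof.times, prof.concentrations):
                rows.append({"subject_id": s.subject_id, "medium": prof.medium,
                             "time": t, "pg_ml": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_melatonin(path) -> dict:
    """Long melatonin CSV -> {(subject_id, medium): MelatoninProfile}."""
    df = pd.read_csv(path)
    out = {}
    for (sid, medium), grp in df.groupby(["subject_id", "medium"], sort=True):
        grp = grp.sort_values("time")
        out[(sid, medium)] = MelatoninProfile(
            sid, medium, grp["time"].to_numpy(float), grp["pg_ml"].to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def _hours_to_timestamp(hours: float) -> str:
    return (_BASE_DATE + _dt.timedelta(hours=float(hours))).isoformat()


def _timestamp_to_hours(ts: str) -> float:
    return (pd.Timestamp(ts).to_pydatetime() - _BASE_DATE).total_seconds() / 3600.0


def _hours_to_hhmm(hours: float) -> str:
    h = float(hours) % 24.0
    m = int(round(h * 60)) % 1440
    return f"{m // 60:02d}:{m % 60:02d}"


def write_activity(cohort, epochs_path, rest_path) -> None:
    eframes, rrows = [], []
    for s in cohort.subjects:
        a = s.activity
        ts = [_hours_to_timestamp(h) for h in a.epoch_start_hours]
        eframes.append(pd.DataFrame({"subject_id": s.subject_id, "timestamp": ts,
                                     "counts": a.counts}))
        for bed, wake in a.rest_intervals:
            date = (_BASE_DATE + _dt.timedelta(hours=float(bed))).date().isoformat()
            rrows.append({"subject_id": s.subject_id, "date": date,
                          "bedtime": _hours_to_hhmm(bed),
                          "waketime": _hours_to_hhmm(wake),
                          "bed_hours": bed, "wake_hours": wake})
    pd.concat(eframes, ignore_index=True).to_csv(epochs_path, index=False)
    pd.DataFrame(rrows).to_csv(rest_path, index=False)


def read_activity(epochs_path, rest_path) -> dict:
    """Epoch + rest-interval CSVs -> {subject_id: ActivitySeries}."""
    epochs = pd.read_csv(epochs_path)
    rest = pd.read_csv(rest_path)
    out = {}
    for sid, grp in epochs.groupby("subject_id", sort=True):
        hours = np.array([_timestamp_to_hours(t) for t in grp["timestamp"]])
        order = np.argsort(hours)
        hours, counts = hours[order], grp["counts"].to_numpy(float)[order]
        if hours.size > 1:
            epoch_minutes = int(round((hours[1] - hours[0]) * 60))
        else:
            epoch_minutes = 1
        rsub = rest[rest["subject_id"] == sid]
        if {"bed_hours", "wake_hours"}.issubset(rsub.columns):
            intervals = list(zip(rsub["bed_hours"].astype(float),
                                 rsub["wake_hours"].astype(float)))
        else:
            intervals = []
            for row in rsub.itertuples(index=False):
                day0 = (_dt.datetime.fromisoformat(row.date) - _BASE_DATE).days * 24.0
                bh, bm = map(int, row.bedtime.split(":"))
                wh, wm = map(int, row.waketime.split(":"))
                bed = day0 + bh + bm / 60.0
                wake = day0 + wh + wm / 60.0
                if wake <= bed:
                    wake += 24.0
                intervals.append((bed, wake))
        out[sid] = ActivitySeries(sid, hours, epoch_minutes, counts, intervals)
    return out
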