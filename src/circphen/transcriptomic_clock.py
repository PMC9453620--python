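"""Circadian clock-time prediction from within-subject-normalized blood expression.

The predictor maps a normalized expression vector to a point on the 24 h
circle: two ridge regressions fit cos(2*pi*t/24) and sin(2*pi*t/24) on the
training expression, and the predicted time is atan2 of the two fitted
coordinates. Within-subject normalization (centering each gene on the
subject's own mean across that subject's samples) removes inter-individual
baseline differences, which is what makes a two-sample protocol workable.

The signed difference between predicted and true sampling time is the
*transcriptomic angle* (hours in [-12, 12); positive = internal clock ahead
of local time, i.e. advanced phase). Averaging a subject's AM and PM angles
gives the subject-level phenotype, and the fraction of samples predicted
within a tolerance h, swept over h in [0, 12], gives the tolerance-accuracy
curve whose normalized area (nAUC) summarizes overall accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.linear_model import Ridge

from .errors import (DegenerateInputError, MissingGeneError,
                     SingularDesignError, UndefinedPhaseError)

HOURS = 24.0
_OMEGA = 2.0 * np.pi / HOURS

PENALTY_GRID = (1e-2, 1e-1, 1.0, 10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    gene_ids: list
    w_cos: np.ndarray
    w_sin: np.ndarray
    b_cos: float
    b_sin: float
    ridge_penalty: float
    training_meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "gene_ids": list(self.gene_ids),
            "w_cos": np.asarray(self.w_cos).tolist(),
            "w_sin": np.asarray(self.w_sin).tolist(),
            "b_cos": self.b_cos,
            "b_sin": self.b_sin,
            "ridge_penalty": self.ridge_penalty,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["gene_ids"], np.array(obj["w_cos"]), np.array(obj["w_sin"]),
                   float(obj["b_cos"]), float(obj["b_sin"]),
                   float(obj["ridge_penalty"]), obj.get("training_meta", {}))


@dataclass
class AnglePhenotype:
    subject_id: str
    angle_am: Optional[float]
    angle_pm: Optional[float]
    angle_mean: float
    single_session: bool = False


@dataclass
class AccuracyCurve:
    tolerances: np.ndarray      # hours, ascending on [0, 12]
    fraction_correct: np.ndarray
    nauc: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def within_subject_normalize(samples_by_subject: dict) -> dict:
    """Center each gene on the subject's own mean across that subject's samples.

    Parameters
    ----------
    samples_by_subject : dict
        subject_id -> list of ExpressionSample (or any objects with a
        ``values`` array attribute).

    Returns
    -------
    dict
        subject_id -> list of (sample, normalized_values) in input order.
        Subjects with a single sample normalize to the zero vector, which
        carries no timing signal; they are returned but flagged via the
        companion set in :func:`single_sample_subjects`.
    """
    out = {}
    for sid, samples in samples_by_subject.items():
        if len(samples) == 0:
            raise ValueError(f"subject {sid!r} has no samples")
        mat = np.vstack([np.asarray(s.values, dtype=float) for s in samples])
        centered = mat - mat.mean(axis=0, keepdims=True)
        out[sid] = [(s, centered[i]) for i, s in enumerate(samples)]
    return out


def single_sample_subjects(samples_by_subject: dict) -> set:
    """Subjects for whom normalization destroys the signal (one sample only)."""
    return {sid for sid, ss in samples_by_subject.items() if len(ss) == 1}


def _design(normalized: dict):
    X, t, subj = [], [], []
    for sid, pairs in normalized.items():
        for sample, vals in pairs:
            X.append(vals)
            t.append(sample.clock_time)
            subj.append(sid)
    return np.vstack(X), np.asarray(t, dtype=float), np.asarray(subj)


def train_clock(normalized: dict, ridge_penalty=1.0, seed: int = 0) -> ClockModel:
    """Fit the two ridge regressions onto (cos, sin) of sampling time.

    ``ridge_penalty`` may be a number or ``"auto"``, in which case the penalty
    is chosen from a small grid by leave-one-subject-out cross-validation
    minimizing mean absolute angular error. Both component regressions share
    the penalty. Deterministic given its inputs.
    """
    X, t, subj = _design(normalized)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.unique(np.round(t, 9)).size < 2:
        raise ValueError("need at least 2 distinct clock times in training set")

    gene_ids = _training_gene_ids(normalized)

    if isinstance(ridge_penalty, str):
        if ridge_penalty != "auto":
            raise ValueError(f"unknown penalty spec {ridge_penalty!r}")
        ridge_penalty = _select_penalty(X, t, subj)

    ridge_penalty = float(ridge_penalty)
    if ridge_penalty < 0:
        raise ValueError("ridge_penalty must be >= 0")
    if ridge_penalty == 0.0:
        Xc = X - X.mean(axis=0, keepdims=True)
        if np.linalg.matrix_rank(Xc) < X.shape[1]:
            raise SingularDesignError(
                "design is rank-deficient; use ridge_penalty > 0")

    y = np.column_stack([np.cos(_OMEGA * t), np.sin(_OMEGA * t)])
    fit = Ridge(alpha=ridge_penalty, fit_intercept=True).fit(X, y)
    w = fit.coef_
    b = fit.intercept_
    return ClockModel(gene_ids, w[0].copy(), w[1].copy(), float(b[0]), float(b[1]),
                      ridge_penalty,
                      {"seed": int(seed), "n_training_samples": int(X.shape[0])})


def _training_gene_ids(normalized: dict) -> list:
    for pairs in normalized.values():
        for sample, _ in pairs:
            ids = getattr(sample, "gene_ids", None)
            if ids is not None:
                return list(ids)
            return [f"G{i+1:04d}" for i in range(len(sample.values))]
    raise ValueError("empty training set")


def _select_penalty(X, t, subj, grid=PENALTY_GRID) -> float:
    """Leave-one-subject-out grid search on mean absolute angular error."""
    y = np.column_stack([np.cos(_OMEGA * t), np.sin(_OMEGA * t)])
    best, best_err = grid[0], np.inf
    for alpha in grid:
        errs = []
        for sid in np.unique(subj):
            hold = subj == sid
            if hold.all() or (~hold).sum() < 2:
                continue
            fit = Ridge(alpha=alpha, fit_intercept=True).fit(X[~hold], y[~hold])
            pred = fit.predict(X[hold])
            pred_t = (np.arctan2(pred[:, 1], pred[:, 0]) / _OMEGA) % HOURS
            errs.extend(abs(signed_angle(pt, tt)) for pt, tt in zip(pred_t, t[hold]))
        mean_err = float(np.mean(errs)) if errs else np.inf
        if mean_err < best_err:
            best, best_err = alpha, mean_err
    return float(best)


def predict_time(model: ClockModel, values, gene_ids=None) -> float:
    """Transcriptomic time (hours in [0, 24)) for one normalized sample.

    Genes are matched to the model by identifier; order does not matter.
    """
    values = np.asarray(values, dtype=float)
    if gene_ids is not None:
        index = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in model.gene_ids if g not in index]
        if missing:
            raise MissingGeneError(missing)
        values = values[[index[g] for g in model.gene_ids]]
    elif values.shape[0] != len(model.gene_ids):
        raise MissingGeneError(model.gene_ids[values.shape[0]:])
    c = float(values @ model.w_cos + model.b_cos)
    s = float(values @ model.w_sin + model.b_sin)
    if c == 0.0 and s == 0.0:
        raise UndefinedPhaseError("predicted circular coordinates are (0, 0)")
    return float((np.arctan2(s, c) / _OMEGA) % HOURS)


def signed_angle(predicted: float, true: float) -> float:
    """Signed circular difference predicted - true, hours in [-12, 12).

    Positive means the predicted (internal) time runs ahead of local clock
    time, i.e. an advanced circadian phase. The antipodal difference of
    exactly 12 h maps to -12 by convention.
    """
    for name, v in (("predicted", predicted), ("true", true)):
        if not (0.0 <= v < HOURS):
            raise ValueError(f"{name} time {v!r} outside [0, 24)")
    return float(((predicted - true + 12.0) % HOURS) - 12.0)


def subject_angle(angles_by_session: dict) -> AnglePhenotype:
    """Average a subject's per-session signed angles into one phenotype.

    The AM and PM angles are averaged arithmetically (safe while far from the
    +/-12 h boundary); a subject with one session is flagged as less reliable.
    """
    d = dict(angles_by_session)
    subject_id = d.pop("subject_id", "")
    sessions = {k: v for k, v in d.items() if v is not None}
    if not sessions:
        raise ValueError("no session angles provided")
    am = sessions.get("AM")
    pm = sessions.get("PM")
    mean = float(np.mean(list(sessions.values())))
    return AnglePhenotype(subject_id, am, pm, mean, single_session=len(sessions) == 1)


def accuracy_curve(angles, grid_step: float = 0.1) -> AccuracyCurve:
    """Tolerance-accuracy curve and its normalized area (nAUC).

    fraction_correct(h) is the proportion of samples whose absolute angle is
    <= h; the curve is evaluated on an ascending grid over [0, 12]. The nAUC
    is the exact area under the empirical step curve divided by 12, computed
    in closed form as 1 - mean(|angle|)/12, so a perfect predictor scores 1
    and a uniformly wrong one 0.5.
    """
    a = np.abs(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle input")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if np.any(a > 12.0):
        raise ValueError("angles must lie in [-12, 12]")
    tol = np.arange(0.0, 12.0 + grid_step / 2.0, grid_step)
    if tol[-1] < 12.0:
        tol = np.append(tol, 12.0)
    frac = (a[None, :] <= tol[:, None]).mean(axis=1)
    nauc = float(1.0 - a.mean() / 12.0)
    return AccuracyCurve(tol, frac, nauc)
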