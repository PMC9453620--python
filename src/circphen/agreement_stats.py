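"""Method-agreement statistics between the transcriptomic angle and other phenotypes.

Pearson and covariate-adjusted partial correlations, z-scored Bland-Altman
limits of agreement, two-group comparisons (equal-variance t-test for
continuous variables, chi-squared without continuity correction for
categorical ones) and a Kolmogorov-Smirnov normality check. Complete-case
analysis throughout; missingness is reported per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

_RESIDUAL_VAR_TOL = 1e-12


@dataclass
class CorrelationResult:
    variable_pair: tuple
    r: float
    p_value: float
    n: int
    covariates: tuple = ()
    n_missing: int = 0


@dataclass
class BlandAltmanResult:
    mean_difference: float      # z-units
    loa_lower: float
    loa_upper: float
    averages: np.ndarray        # per-subject (z(x)+z(y))/2
    differences: np.ndarray     # per-subject z(x)-z(y)
    orientation: int = 1        # sign applied to y before z-scoring


def _complete_cases(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("inputs must have equal length")
    mask = np.ones(n, dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return [c[mask] for c in cols], int(n - mask.sum())


def partial_correlation(x, y, covariates=None, labels=("x", "y"),
                        covariate_labels=()) -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on an intercept plus the covariates by
    least squares; the Pearson correlation of the residuals is tested against
    a t distribution with n - 2 - k degrees of freedom. With no covariates
    this reduces exactly to the plain Pearson correlation.
    """
    covs = [] if covariates is None else [np.asarray(c, float) for c in covariates]
    cols, n_missing = _complete_cases(x, y, *covs)
    xv, yv, covs = cols[0], cols[1], cols[2:]
    k = len(covs)
    n = xv.size
    if n <= 2 + k:
        raise ValueError(f"need more than {2 + k} complete cases, got {n}")

    Z = np.column_stack([np.ones(n)] + covs)
    rx = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
    ry = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    for name, res, orig in ((labels[0], rx, xv), (labels[1], ry, yv)):
        scale = max(float(np.var(orig)), 1.0)
        if float(np.var(res)) <= _RESIDUAL_VAR_TOL * scale:
            raise DegenerateInputError(
                f"{name} has ~zero residual variance after adjustment")

    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(tuple(labels), r, p, n,
                             tuple(covariate_labels), n_missing)


def pearson_correlation(x, y, labels=("x", "y")) -> CorrelationResult:
    """Plain Pearson correlation (partial correlation with no covariates)."""
    return partial_correlation(x, y, None, labels=labels)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance input to Bland-Altman")
    return (v - v.mean()) / sd


def bland_altman(x, y, orientation: int = 1) -> BlandAltmanResult:
    """Z-scored Bland-Altman agreement between two phase measures.

    ``orientation`` = -1 negates y before z-scoring so both measures point the
    same way (e.g. clock-time markers where later = delayed are flipped to the
    angle's "positive = advanced" direction). Both series are then converted
    to z-scores; the mean difference of complete-case z-scores is identically
    zero, so the informative output is the 1.96 * SD limits of agreement.
    """
    if orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    (xv, yv), _ = _complete_cases(x, y)
    if xv.size < 3:
        raise ValueError("need at least 3 complete pairs")
    zx = _zscore(xv)
    zy = _zscore(orientation * yv)
    d = zx - zy
    mean_d = float(d.mean())
    sd_d = float(np.std(d, ddof=1))
    return BlandAltmanResult(mean_d, mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d,
                             (zx + zy) / 2.0, d, orientation)


def group_compare(values, group_labels, kind: str = "auto"):
    """Two-group comparison: Student's t (continuous) or chi-squared (categorical).

    Returns (statistic, p_value, test_name). ``kind`` may be "continuous",
    "categorical", or "auto" (categorical when values take <= 2 distinct
    levels or are non-numeric). The t-test assumes equal variances; the
    chi-squared test applies no continuity correction.
    """
    values = np.asarray(values)
    groups = np.asarray(group_labels)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")

    if kind == "auto":
        numeric = np.issubdtype(values.dtype, np.number)
        kind = "continuous" if numeric and np.unique(values).size > 2 else "categorical"

    if kind == "continuous":
        a = values[groups == levels[0]].astype(float)
        b = values[groups == levels[1]].astype(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 observations for a t-test")
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return float(stat), float(p), "student_t"
    if kind == "categorical":
        cats = np.unique(values)
        table = np.array([[np.sum((groups == g) & (values == c)) for c in cats]
                          for g in levels], dtype=float)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi_squared"
    raise ValueError(f"unknown kind {kind!r}")


def normality_check(x):
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample's own mean and SD, so the reported p
    is anti-conservative (Lilliefors caveat); a warning string accompanies
    the result. Returns (statistic, p_value, warning).
    """
    (xv,), _ = _complete_cases(x)
    if xv.size < 5:
        raise ValueError("need at least 5 observations")
    sd = np.std(xv, ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant input: normality undefined")
    stat, p = stats.kstest(xv, "norm", args=(xv.mean(), sd))
    warning = ("reference parameters estimated from the sample; "
               "p-value is anti-conservative (Lilliefors caveat)")
    return float(stat), float(p), warning
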