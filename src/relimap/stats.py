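"""Scalar reliability statistics: ANOVA variance decomposition and ICC.

This module is the numerical core applied per voxel by :mod:`relimap.maps`.
It implements the two-way (subject x occasion, one observation per cell) and
one-way random-effects ANOVA decompositions, the single-measure intraclass
correlation coefficients ICC(1), ICC(2,1) and ICC(3,1) in their general-k
Shrout--Fleiss forms, F-distribution confidence bounds (McGraw & Wong
conventions for ICC(2,1)), precision-weighted fixed-effects averaging, GLM
contrast efficiency, and the t -> Cohen's d conversion.

Notation
--------
For ``n`` subjects measured on ``k`` occasions:

* ``MSBS``  -- mean square between subjects,
* ``MSBM``  -- mean square between measures (occasions),
* ``MSE``   -- residual (error) mean square of the two-way fit,
* ``MSW``   -- within-subject mean square of the one-way fit,
* ``sigma2_between`` (between-subject variance)  = (MSBS - MSE) / k,
* ``sigma2_within``  (within-subject variance)   = MSE,
* ``sigma2_measure`` (between-measure variance)  = (MSBM - MSE) / n.

For k = 2 the consistency ICC reduces to the familiar
``(MSBS - MSE) / (MSBS + MSE) = sigma2_between / (sigma2_between + sigma2_within)``.

Degenerate input (zero total variance) yields a NaN estimate with an explicit
``degenerate`` flag rather than an arbitrary 0 or 1, so that voxel maps can
propagate missingness. Negative ICC estimates are returned untruncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ReliabilityError",
    "InvalidDesignError",
    "SingularDesignError",
    "ICC_TYPES",
    "MeasurementMatrix",
    "TwoWayAnova",
    "OneWayAnova",
    "VarianceComponents",
    "IccEstimate",
    "decompose_twoway",
    "decompose_oneway",
    "icc",
    "icc_confidence_interval",
    "fixed_effects_combine",
    "contrast_efficiency",
    "t_to_cohens_d",
    "pearson_r",
]

ICC_TYPES = ("icc_1", "icc_2", "icc_3")


class ReliabilityError(Exception):
    """Base class for errors raised by relimap."""


class InvalidDesignError(ReliabilityError, ValueError):
    """Measurement design unusable (too few subjects/occasions, missing cells)."""


class SingularDesignError(ReliabilityError, ValueError):
    """Design matrix is rank deficient; the contrast variance is undefined."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementMatrix:
    """Complete n_subjects x k_occasions table of one measure's values.

    Rows are subjects, columns are measurement occasions (runs or sessions).
    The design must be complete: at least 2 subjects, at least 2 occasions,
    and no missing cells.
    """

    values: np.ndarray
    subject_ids: tuple = None
    occasion_ids: tuple = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InvalidDesignError(
                f"measurement matrix must be 2-D (subjects x occasions), got ndim={vals.ndim}"
            )
        n, k = vals.shape
        if n < 2 or k < 2:
            raise InvalidDesignError(
                f"need at least 2 subjects and 2 occasions, got {n} x {k}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidDesignError("measurement matrix contains non-finite cells")
        object.__setattr__(self, "values", vals)
        subj = self.subject_ids or tuple(f"sub-{i + 1:02d}" for i in range(n))
        occ = self.occasion_ids or tuple(f"occ-{j + 1}" for j in range(k))
        if len(subj) != n or len(occ) != k:
            raise InvalidDesignError("label lengths do not match matrix shape")
        object.__setattr__(self, "subject_ids", tuple(subj))
        object.__setattr__(self, "occasion_ids", tuple(occ))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_occasions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_occasions(cls, occasions: Sequence[Sequence[float]], **kw) -> "MeasurementMatrix":
        """Build from per-occasion vectors (each of length n_subjects)."""
        cols = [np.asarray(c, dtype=float) for c in occasions]
        if len({c.shape for c in cols}) != 1:
            raise InvalidDesignError("occasion vectors differ in length")
        return cls(np.column_stack(cols), **kw)


@dataclass(frozen=True)
class TwoWayAnova:
    """Two-way (subject x occasion) ANOVA table, one observation per cell."""

    ms_between_subject: float
    ms_between_measure: float
    ms_error: float
    ss_total: float
    ss_subject: float
    ss_measure: float
    ss_error: float
    df_subject: int
    df_measure: int
    df_error: int
    n_subjects: int
    k_occasions: int


@dataclass(frozen=True)
class OneWayAnova:
    """One-way (subject) ANOVA table; occasions pooled into within-subject error."""

    ms_between_subject: float
    ms_within: float
    ss_total: float
    ss_subject: float
    ss_within: float
    df_subject: int
    df_within: int
    n_subjects: int
    k_occasions: int


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA variance components; sigma2_between may be negative (untruncated)."""

    sigma2_between: float
    sigma2_within: float
    sigma2_measure: Optional[float] = None


@dataclass(frozen=True)
class IccEstimate:
    icc_type: str
    estimate: float
    lower: float
    upper: float
    alpha: float
    components: VarianceComponents
    degenerate: bool = False
    n_subjects: int = 0
    k_occasions: int = 0


# ---------------------------------------------------------------------------
# vectorised kernels (shared with relimap.maps); trailing axes are voxels
# ---------------------------------------------------------------------------


def _twoway_tables(data: np.ndarray) -> dict:
    """Sums of squares / mean squares of the two-way fit, vectorised.

    ``data`` has shape (n, k, ...); statistics are returned with shape
    ``data.shape[2:]``. SS are computed from centered sums (not by
    subtraction) so every term is nonnegative in floating point.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    subj_mean = data.mean(axis=1)
    meas_mean = data.mean(axis=0)
    ss_subject = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_measure = n * ((meas_mean - grand) ** 2).sum(axis=0)
    resid = data - subj_mean[:, None] - meas_mean[None, :] + grand
    ss_error = (resid**2).sum(axis=(0, 1))
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    return {
        "n": n,
        "k": k,
        "ss_subject": ss_subject,
        "ss_measure": ss_measure,
        "ss_error": ss_error,
        "ss_total": ss_total,
        "msbs": ss_subject / (n - 1),
        "msbm": ss_measure / (k - 1),
        "mse": ss_error / ((n - 1) * (k - 1)),
        "msw": (ss_measure + ss_error) / (n * (k - 1)),
    }


def _icc_point(t: dict, icc_type: str):
    """Point estimate plus variance components from the mean-square table."""
    n, k = t["n"], t["k"]
    msbs, msbm, mse, msw = t["msbs"], t["msbm"], t["mse"], t["msw"]
    with np.errstate(divide="ignore", invalid="ignore"):
        if icc_type == "icc_3":
            est = (msbs - mse) / (msbs + (k - 1) * mse)
        elif icc_type == "icc_2":
            est = (msbs - mse) / (msbs + (k - 1) * mse + k * (msbm - mse) / n)
        elif icc_type == "icc_1":
            est = (msbs - msw) / (msbs + (k - 1) * msw)
        else:
            raise ValueError(f"unknown icc_type {icc_type!r}; expected one of {ICC_TYPES}")
        sigma2_between = (msbs - mse) / k
        sigma2_measure = (msbm - mse) / n
    degenerate = (t["ss_total"] == 0) | ~np.isfinite(est)
    est = np.where(degenerate, np.nan, est)
    return est, sigma2_between, mse, sigma2_measure, degenerate


def _icc_bounds(t: dict, est, icc_type: str, alpha: float):
    """F-based confidence bounds, vectorised; NaN where the estimate is NaN.

    icc_3 / icc_1 follow the Shrout--Fleiss pivot: with F the observed
    variance ratio, FL = F / F_{1-a/2}(df1, df2) and FU = F * F_{1-a/2}(df2, df1),
    each mapped through (F* - 1)/(F* + k - 1). icc_2 uses the McGraw--Wong
    Satterthwaite degrees of freedom.
    """
    n, k = t["n"], t["k"]
    q = 1.0 - alpha / 2.0
    msbs, msbm, mse, msw = t["msbs"], t["msbm"], t["mse"], t["msw"]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if icc_type in ("icc_3", "icc_1"):
            if icc_type == "icc_3":
                denom_ms, df2 = mse, (n - 1) * (k - 1)
            else:
                denom_ms, df2 = msw, n * (k - 1)
            df1 = n - 1
            fobs = msbs / denom_ms
            fl = fobs / sps.f.ppf(q, df1, df2)
            fu = fobs * sps.f.ppf(q, df2, df1)
            lower = (fl - 1.0) / (fl + k - 1.0)
            upper = (fu - 1.0) / (fu + k - 1.0)
            # perfect consistency: zero error variance with real subject spread
            perfect = (denom_ms == 0) & (msbs > 0)
            lower = np.where(perfect, 1.0, lower)
            upper = np.where(perfect, 1.0, upper)
        else:  # icc_2, McGraw & Wong (1996)
            a = k * est / (n * (1.0 - est))
            b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est))
            v = (a * msbm + b * mse) ** 2 / (
                (a * msbm) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
            )
            f_l = sps.f.ppf(q, n - 1.0, v)
            f_u = sps.f.ppf(q, v, n - 1.0)
            lower = (
                n * (msbs - f_l * mse)
                / (f_l * (k * msbm + (k * n - k - n) * mse) + n * msbs)
            )
            upper = (
                n * (f_u * msbs - mse)
                / (k * msbm + (k * n - k - n) * mse + n * f_u * msbs)
            )
            perfect = est == 1.0
            lower = np.where(perfect, 1.0, lower)
            upper = np.where(perfect, 1.0, upper)

    bad = ~np.isfinite(np.asarray(est, dtype=float))
    lower = np.where(bad, np.nan, lower)
    upper = np.where(bad, np.nan, upper)
    # the interval always contains the point estimate
    lower = np.fmin(lower, est)
    upper = np.fmax(upper, est)
    return lower, upper


# ---------------------------------------------------------------------------
# public scalar operations
# ---------------------------------------------------------------------------


def decompose_twoway(m: MeasurementMatrix) -> TwoWayAnova:
    """Two-way ANOVA of a complete subject x occasion matrix.

    The sums of squares partition the total exactly:
    ``ss_subject + ss_measure + ss_error == ss_total``.
    """
    t = _twoway_tables(m.values)
    n, k = t["n"], t["k"]
    return TwoWayAnova(
        ms_between_subject=float(t["msbs"]),
        ms_between_measure=float(t["msbm"]),
        ms_error=float(t["mse"]),
        ss_total=float(t["ss_total"]),
        ss_subject=float(t["ss_subject"]),
        ss_measure=float(t["ss_measure"]),
        ss_error=float(t["ss_error"]),
        df_subject=n - 1,
        df_measure=k - 1,
        df_error=(n - 1) * (k - 1),
        n_subjects=n,
        k_occasions=k,
    )


def decompose_oneway(m: MeasurementMatrix) -> OneWayAnova:
    """One-way ANOVA: occasion and residual variation pooled within subjects."""
    t = _twoway_tables(m.values)
    n, k = t["n"], t["k"]
    return OneWayAnova(
        ms_between_subject=float(t["msbs"]),
        ms_within=float(t["msw"]),
        ss_total=float(t["ss_total"]),
        ss_subject=float(t["ss_subject"]),
        ss_within=float(t["ss_measure"] + t["ss_error"]),
        df_subject=n - 1,
        df_within=n * (k - 1),
        n_subjects=n,
        k_occasions=k,
    )


def icc(m: MeasurementMatrix, icc_type: str = "icc_3", alpha: float = 0.05) -> IccEstimate:
    """Single-measure intraclass correlation with F-based confidence bounds.

    Parameters
    ----------
    m
        Complete subject x occasion measurement matrix.
    icc_type
        ``"icc_1"`` (one-way random), ``"icc_2"`` (two-way random, absolute
        agreement, ICC(2,1)) or ``"icc_3"`` (two-way mixed, consistency,
        ICC(3,1); the default).
    alpha
        Two-sided confidence level is ``1 - alpha`` (default 95%).

    Returns
    -------
    IccEstimate
        Point estimate, bounds, variance components and a ``degenerate`` flag.
        Zero total variance gives NaN estimate/bounds with ``degenerate=True``;
        negative estimates are not truncated.
    """
    if icc_type not in ICC_TYPES:
        raise ValueError(f"unknown icc_type {icc_type!r}; expected one of {ICC_TYPES}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    t = _twoway_tables(m.values)
    est, s2b, s2w, s2m, degen = _icc_point(t, icc_type)
    if bool(degen):
        lower = upper = float("nan")
    else:
        lower, upper = _icc_bounds(t, est, icc_type, alpha)
    comps = VarianceComponents(
        sigma2_between=float(s2b),
        sigma2_within=float(s2w),
        sigma2_measure=float(s2m) if icc_type == "icc_2" else None,
    )
    return IccEstimate(
        icc_type=icc_type,
        estimate=float(est),
        lower=float(lower),
        upper=float(upper),
        alpha=alpha,
        components=comps,
        degenerate=bool(degen),
        n_subjects=t["n"],
        k_occasions=t["k"],
    )


def icc_confidence_interval(anova, icc_type: str, n: int, k: int, alpha: float = 0.05):
    """Confidence bounds for an ICC from an already-computed ANOVA table.

    Accepts a :class:`TwoWayAnova` for any type or a :class:`OneWayAnova` for
    ``icc_1``. Returns ``(lower, upper)``.
    """
    if icc_type not in ICC_TYPES:
        raise ValueError(f"unknown icc_type {icc_type!r}")
    if isinstance(anova, OneWayAnova):
        if icc_type != "icc_1":
            raise ValueError("a one-way table only supports icc_1")
        msw = anova.ms_within
        ss_measure = np.nan
        mse = np.nan
        msbm = np.nan
    else:
        ss_measure = anova.ss_measure
        mse = anova.ms_error
        msbm = anova.ms_between_measure
        msw = (anova.ss_measure + anova.ss_error) / (n * (k - 1))
    t = {
        "n": n,
        "k": k,
        "msbs": np.asarray(anova.ms_between_subject, dtype=float),
        "msbm": np.asarray(msbm, dtype=float),
        "mse": np.asarray(mse, dtype=float),
        "msw": np.asarray(msw, dtype=float),
        "ss_total": np.asarray(anova.ss_total, dtype=float),
    }
    est, *_ , degen = _icc_point(t, icc_type)
    if bool(degen):
        return float("nan"), float("nan")
    lower, upper = _icc_bounds(t, est, icc_type, alpha)
    return float(lower), float(upper)


def fixed_effects_combine(betas: Sequence[float], variances: Sequence[float]):
    """Precision-weighted fixed-effects combination of run-level estimates.

    ``beta = sum(b_i / v_i) / sum(1 / v_i)`` and ``variance = 1 / sum(1 / v_i)``.
    Used to average the two run estimates of a session into one session-level
    estimate, weighting each run by its precision.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.shape != v.shape or b.ndim != 1 or b.size < 1:
        raise ValueError("betas and variances must be equal-length 1-D with >= 1 entry")
    if np.any(v <= 0):
        raise ValueError("all variances must be strictly positive")
    w = 1.0 / v
    return float((b * w).sum() / w.sum()), float(1.0 / w.sum())


def contrast_efficiency(design: np.ndarray, contrast: Sequence[float]) -> float:
    """GLM contrast efficiency ``1 / (c (X'X)^{-1} c')``.

    Higher values mean the design estimates the contrast more precisely.
    Raises :class:`SingularDesignError` when ``X`` is rank deficient.
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    p = X.shape[1]
    if c.shape != (p,):
        raise ValueError(f"contrast length {c.shape} does not match {p} design columns")
    if not np.any(c):
        raise ValueError("contrast must not be all zero")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    quad = float(c @ np.linalg.solve(X.T @ X, c))
    return 1.0 / quad


def t_to_cohens_d(t: float, n: int) -> float:
    """Convert a one-sample group t statistic to Cohen's d: ``d = t / sqrt(N)``."""
    if int(n) < 1 or int(n) != n:
        raise ValueError("N must be a positive integer")
    return float(t) / math.sqrt(n)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either input has zero variance."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)
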