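"""Behavioral adaptation indices and task-performance measures.

The degree to which a subject adapts to reward variability is quantified by
regressing a per-SD quantity (fitted learning rates here; neural coding
slopes in :mod:`rpeadapt.neural`) on the inverse SD:

    value(SD) = beta0 + beta1 * SD^-1

The R^2 of this regression is the adaptation index (Omega for learning
rates, Psi for coding slopes): the better SD^-1 predicts the per-SD values,
the stronger the adaptation.  Task performance is the mean absolute
deviation of predictions from the condition's expected value,
|prediction - EV|, which penalises both unstable and inaccurate prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult


@dataclass(frozen=True)
class AdaptationResult:
    """Simple regression of per-SD values on an SD contrast.

    ``r_squared`` is the adaptation index.  With three SD levels and two
    parameters it is well defined unless the response is constant, in which
    case it is defined as 0 and ``degenerate`` is set.
    """

    beta0: float
    beta1: float
    r_squared: float
    predictor_kind: str = "inverse-sd"
    degenerate: bool = False


def _simple_ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, bool]:
    """Closed-form simple regression; returns (b0, b1, r2, degenerate)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("predictor has no variance")
    sxy = float(((x - xm) * (y - ym)).sum())
    b1 = sxy / sxx
    b0 = ym - b1 * xm
    sst = float(((y - ym) ** 2).sum())
    # constant response (up to fp rounding): R^2 defined as 0
    if sst <= 1e-14 * len(y) * max(1.0, ym * ym):
        return float(b0), float(b1), 0.0, True
    sse = float(((y - b0 - b1 * x) ** 2).sum())
    r2 = 1.0 - sse / sst
    return float(b0), float(b1), min(1.0, max(0.0, r2)), False


def behavioral_adaptation(per_sd_values: Mapping[float, float]
                          ) -> AdaptationResult:
    """Adaptation index: OLS of per-SD values on SD^-1.

    ``per_sd_values`` maps each SD (at least three distinct levels) to the
    subject's value at that SD (e.g. the fitted initial learning rate).
    """
    if len(per_sd_values) < 3:
        raise ValueError("need values for at least 3 distinct SDs")
    sds = np.array(sorted(per_sd_values), dtype=float)
    if np.any(sds <= 0):
        raise ValueError("SDs must be positive")
    y = np.array([per_sd_values[sd] for sd in sds], dtype=float)
    b0, b1, r2, degen = _simple_ols(1.0 / sds, y)
    return AdaptationResult(beta0=b0, beta1=b1, r_squared=r2,
                            predictor_kind="inverse-sd", degenerate=degen)


def compare_contrast_fits(per_sd_values: Mapping[float, float]
                          ) -> Tuple[float, float]:
    """R^2 under a non-linear (1/SD) versus a linear (1, 0, -1) contrast.

    Both predictors are zero-centred and fitted with an intercept to the same
    three per-SD values (ascending SD); returns
    ``(r2_nonlinear, r2_linear)``.  Whichever shape generated the values
    achieves the higher R^2.
    """
    if len(per_sd_values) != 3:
        raise ValueError("contrast comparison requires exactly 3 SD levels")
    sds = np.array(sorted(per_sd_values), dtype=float)
    y = np.array([per_sd_values[sd] for sd in sds], dtype=float)
    x_nl = 1.0 / sds
    x_nl = x_nl - x_nl.mean()
    x_lin = np.array([1.0, 0.0, -1.0])
    _, _, r2_nl, _ = _simple_ols(x_nl, y)
    _, _, r2_lin, _ = _simple_ols(x_lin, y)
    return r2_nl, r2_lin


@dataclass(frozen=True)
class PerformanceSummary:
    """Mean absolute performance error |prediction - EV|.

    ``per_subject`` indexes subjects; ``per_condition`` breaks the same
    average down by condition.
    """

    per_subject: pd.Series
    per_condition: pd.DataFrame


def performance_error(trials: pd.DataFrame) -> PerformanceSummary:
    """Performance error |prediction - EV| averaged over non-missed trials."""
    valid = trials[~trials["missed"].astype(bool)].copy()
    if valid.empty:
        raise ValueError("no valid (non-missed) trials")
    valid["abs_error"] = (valid["prediction"] - valid["ev"]).abs()
    per_subject = valid.groupby("subject")["abs_error"].mean()
    per_condition = (
        valid.groupby(["subject", "condition_id", "sd", "ev"], as_index=False)
        ["abs_error"].mean()
    )
    return PerformanceSummary(per_subject=per_subject,
                              per_condition=per_condition)


@dataclass(frozen=True)
class PairedDifference:
    """Per-subject paired differences with a paired t test."""

    differences: pd.Series
    mean_difference: float
    t_stat: float
    p_value: float
    n: int


def context_effect(sd10_with_lower: Sequence[float],
                   sd10_with_higher: Sequence[float]) -> PairedDifference:
    """Contextual effect on the two SD-10 conditions.

    Takes per-subject paired values (e.g. fitted learning rates) for the
    SD-10 condition paired with the lower-SD partner versus the higher-SD
    partner within a session, and tests whether they differ.  For agents
    that adapt to SD itself (not to the within-session context) the mean
    paired difference is approximately zero.
    """
    a = np.asarray(sd10_with_lower, dtype=float)
    b = np.asarray(sd10_with_higher, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired 1-d samples of equal length >= 2")
    diffs = pd.Series(a - b)
    t, p = stats.ttest_rel(a, b)
    return PairedDifference(differences=diffs,
                            mean_difference=float(diffs.mean()),
                            t_stat=float(t), p_value=float(p), n=a.size)


@dataclass(frozen=True)
class AsymmetryResult:
    """Learning-rate asymmetry alpha_neg - alpha_pos from dual-rate RW fits."""

    per_subject: pd.Series
    mean_difference: float
    t_stat: float
    p_value: float


def signed_learning_asymmetry(dual_fits: Mapping[int, FitResult]
                              ) -> AsymmetryResult:
    """Per-subject alpha- minus alpha+ and a one-sample t test of the mean.

    Positive values mean the subject weighted negative prediction errors more
    heavily than positive ones during learning.
    """
    if not dual_fits:
        raise ValueError("no fits supplied")
    diffs = {}
    for s, fit in dual_fits.items():
        if fit.model != "rw_dual":
            raise ValueError(f"subject {s}: expected a dual-rate RW fit, "
                             f"got {fit.model!r}")
        diffs[s] = fit.params.alpha_neg - fit.params.alpha_pos
    per = pd.Series(diffs).sort_index()
    if len(per) >= 2 and per.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(per, 0.0)
    else:
        t, p = math.nan, math.nan
    return AsymmetryResult(per_subject=per, mean_difference=float(per.mean()),
                           t_stat=float(t), p_value=float(p))


def rank_correlation(x: Sequence[float], y: Sequence[float]
                     ) -> Tuple[float, float]:
    """Spearman rank correlation (tie-aware) with its p value.

    Raises on constant input, where the correlation is undefined.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if xa.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def zscore_per_subject(df: pd.DataFrame, value_col: str,
                       subject_col: str = "subject") -> pd.Series:
    """Z-score a column within each subject (population SD).

    Used before cohort-level plots and tests to control for between-subject
    offsets; raw values are retained for the regressions themselves.
    """
    def z(v: pd.Series) -> pd.Series:
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else v * 0.0

    return df.groupby(subject_col)[value_col].transform(z)
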