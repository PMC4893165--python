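"""Synthetic per-trial response amplitudes with configurable adaptive coding.

A scalar stand-in for event-related neural responses to reward outcomes: each
trial's response is a linear function of the trial's prediction error, whose
slope (gain) may adapt to the SD of the active reward distribution,

    response = b * [(1 - psi) + psi * SD_ref / SD] * delta * s(delta) + noise,

with SD_ref = 5 (the narrowest condition).  ``psi = 0`` yields absolute
coding (equal slopes across SDs); ``psi = 1`` yields fully normalised coding
(slope proportional to 1/SD); ``s(delta)`` optionally amplifies responses to
negative prediction errors.  A per-phase multiplier on psi lets adaptation
ramp up across early/middle/late trials.  Response units are arbitrary; only
slope ratios and orderings are meaningful.

Slope estimation regresses responses on prediction errors per group (SD x
phase x sign), with reward magnitude partialled out so the slope reflects
prediction-error coding rather than outcome value.  The per-SD slopes feed
the same inverse-SD regression as the behavioral learning rates, yielding the
neural adaptation index Psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adaptation import AdaptationResult, behavioral_adaptation

SD_REF = 5.0

PHASES = ("early", "middle", "late")


class CollinearityError(ValueError):
    """Regressors too collinear for a joint estimate (e.g. a single SD)."""


@dataclass(frozen=True)
class NeuralCohortConfig:
    """Generative settings for one simulated subject's responses.

    ``base_slope`` is the response change per pound of prediction error at
    the reference SD; ``psi`` in [0, 1] the adaptive-coding strength;
    ``noise_sd`` the response-noise scale (response units);
    ``sign_asymmetry`` a multiplicative factor on the slope for negative
    prediction errors; ``phase_ramp`` per-phase multipliers on psi for
    early/middle/late trials (trials beyond the late window use the late
    multiplier).
    """

    base_slope: float = 1.0
    psi: float = 0.5
    noise_sd: float = 3.0
    sign_asymmetry: float = 1.0
    phase_ramp: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi must lie in [0, 1], got {self.psi!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.phase_ramp) != 3:
            raise ValueError("phase_ramp needs one multiplier per phase")


def split_phases(trials: pd.DataFrame) -> pd.DataFrame:
    """Tag trials as early (1-7), middle (8-14) or late (15-21).

    Returns a copy with a ``phase`` column.  Trials beyond the 21-trial
    analysis window (the canonical schedule has a few) are tagged ``post``
    and are excluded from phase-resolved analyses.  Raises if any condition
    has fewer than 21 trials.
    """
    counts = trials.groupby(["subject", "condition_id"])["trial_in_condition"].max()
    short = counts[counts < 21]
    if not short.empty:
        raise ValueError(
            "phase split requires >= 21 trials per condition; short: "
            + ", ".join(f"{s}/{c} ({n})" for (s, c), n in short.items())
        )
    out = trials.copy()
    t = out["trial_in_condition"]
    out["phase"] = np.select(
        [t <= 7, t <= 14, t <= 21], ["early", "middle", "late"], default="post")
    return out


def simulate_responses(trials: pd.DataFrame, config: NeuralCohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Simulate per-trial response amplitudes for one subject's trials.

    Returns a copy of the trial table with a ``response`` column.  Missed
    trials (no prediction error) get NaN responses.
    """
    if "rpe" not in trials.columns:
        raise ValueError("trials must carry a prediction-error column 'rpe'")
    if config.phase_ramp != (1.0, 1.0, 1.0):
        df = split_phases(trials)
        mult = df["phase"].map({"early": config.phase_ramp[0],
                                "middle": config.phase_ramp[1],
                                "late": config.phase_ramp[2],
                                "post": config.phase_ramp[2]}).to_numpy(float)
    else:
        df = trials.copy()
        mult = np.ones(len(df))
    delta = df["rpe"].to_numpy(float)
    sd = df["sd"].to_numpy(float)
    psi_eff = config.psi * mult
    gain = (1.0 - psi_eff) + psi_eff * SD_REF / sd
    sign_factor = np.where(delta < 0, config.sign_asymmetry, 1.0)
    noise = rng.normal(0.0, config.noise_sd, size=len(df))
    df["response"] = config.base_slope * gain * delta * sign_factor + noise
    df.loc[~np.isfinite(delta), "response"] = np.nan
    return df


def simulate_cohort_responses(trials: pd.DataFrame,
                              psi_by_subject: Mapping[int, float],
                              rng: np.random.Generator,
                              **config_kwargs) -> pd.DataFrame:
    """Simulate responses for every subject with subject-specific psi."""
    frames = []
    for subject in sorted(trials["subject"].unique()):
        sub_rng = rng.spawn(1)[0]
        cfg = NeuralCohortConfig(psi=float(psi_by_subject[int(subject)]),
                                 **config_kwargs)
        frames.append(simulate_responses(
            trials[trials["subject"] == subject], cfg, sub_rng))
    return pd.concat(frames, ignore_index=True)


def _group_slope(g: pd.DataFrame, response_col: str,
                 orthogonalize_value: bool) -> Tuple[float, float, float]:
    """(slope, intercept, se) of response on delta within one group."""
    delta = g["rpe"].to_numpy(float)
    resp = g[response_col].to_numpy(float)
    if float(np.std(delta)) == 0.0:
        raise ValueError("degenerate group: constant prediction error")
    if orthogonalize_value:
        X = np.column_stack([np.ones_like(delta), g["reward"].to_numpy(float),
                             delta])
    else:
        X = np.column_stack([np.ones_like(delta), delta])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate group: collinear design")
    beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
    fitted = X @ beta
    dof = len(resp) - X.shape[1]
    if dof > 0:
        sigma_sq = float(((resp - fitted) ** 2).sum()) / dof
        cov = sigma_sq * np.linalg.inv(X.T @ X)
        se = math.sqrt(cov[-1, -1])
    else:
        se = math.nan
    return float(beta[-1]), float(beta[0]), se


def estimate_slopes(responses: pd.DataFrame,
                    by: Sequence[str] = ("sd",),
                    response_col: str = "response",
                    min_trials: int = 3,
                    orthogonalize_value: bool = True) -> pd.DataFrame:
    """Least-squares prediction-error coding slopes per group.

    ``by`` may contain any of ``"subject"``, ``"sd"``, ``"phase"`` and
    ``"sign"``; phase tags are added (and ``post`` trials dropped) when
    grouping by phase, and ``sign`` splits positive (delta >= 0) from
    negative prediction errors.  Reward magnitude is regressed out alongside
    the prediction error by default, so the slope is the partial effect of
    the error independent of outcome value.
    """
    df = responses.dropna(subset=["rpe", response_col]).copy()
    if "phase" in by:
        if "phase" not in df.columns:
            df = split_phases(df)
        df = df[df["phase"].isin(PHASES)]
    if "sign" in by:
        df["sign"] = np.where(df["rpe"] >= 0, "positive", "negative")
    rows = []
    for keys, g in df.groupby(list(by), sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        if len(g) < min_trials:
            raise ValueError(
                f"group {dict(zip(by, keys))} has {len(g)} trials; "
                f"need >= {min_trials}")
        slope, intercept, se = _group_slope(g, response_col,
                                            orthogonalize_value)
        row = dict(zip(by, keys))
        row.update({"slope": slope, "intercept": intercept, "se": se,
                    "n_trials": len(g)})
        rows.append(row)
    return pd.DataFrame(rows)


def neural_adaptation_index(per_sd_slopes: Mapping[float, float]
                            ) -> AdaptationResult:
    """Neural adaptation index Psi: R^2 of per-SD slopes on SD^-1.

    Identical contract to the behavioral index, applied to prediction-error
    coding slopes instead of learning rates.
    """
    return behavioral_adaptation(per_sd_slopes)


def adaptation_by_subject(responses: pd.DataFrame,
                          phase: Optional[str] = None,
                          sign: Optional[str] = None,
                          min_trials: int = 3) -> pd.Series:
    """Per-subject Psi, optionally restricted to one phase or RPE sign."""
    by = ["subject", "sd"]
    if phase is not None:
        by.append("phase")
    if sign is not None:
        by.append("sign")
    slopes = estimate_slopes(responses, by=by, min_trials=min_trials)
    if phase is not None:
        slopes = slopes[slopes["phase"] == phase]
    if sign is not None:
        slopes = slopes[slopes["sign"] == sign]
    out = {}
    for subject, g in slopes.groupby("subject"):
        per_sd = dict(zip(g["sd"], g["slope"]))
        out[subject] = behavioral_adaptation(per_sd).r_squared
    return pd.Series(out).sort_index()


@dataclass(frozen=True)
class NormalizedVsRaw:
    """Joint unique-contribution coefficients of raw and normalised RPEs."""

    per_subject: pd.DataFrame  # columns: coef_raw, coef_norm

    @property
    def mean_raw(self) -> float:
        return float(self.per_subject["coef_raw"].mean())

    @property
    def mean_norm(self) -> float:
        return float(self.per_subject["coef_norm"].mean())


def normalized_vs_raw(responses: pd.DataFrame,
                      response_col: str = "response") -> NormalizedVsRaw:
    """Do responses track raw prediction errors or errors scaled by SD?

    Per subject, both regressors (raw delta and delta/SD) are z-scored across
    all conditions and entered *jointly* (no serial orthogonalisation), along
    with z-scored reward magnitude, so each coefficient reflects uniquely
    explained variance; shared variance is left in the residuals.  With a
    single SD the two regressors are perfectly collinear and a
    :class:`CollinearityError` is raised.
    """
    df = responses.dropna(subset=["rpe", response_col])
    rows = {}
    for subject, g in df.groupby("subject"):
        delta = g["rpe"].to_numpy(float)
        norm = delta / g["sd"].to_numpy(float)
        value = g["reward"].to_numpy(float)

        def z(v: np.ndarray) -> np.ndarray:
            s = v.std()
            if s == 0:
                raise CollinearityError(
                    f"subject {subject}: constant regressor")
            return (v - v.mean()) / s

        zd, zn = z(delta), z(norm)
        if abs(float(np.corrcoef(zd, zn)[0, 1])) > 0.999:
            raise CollinearityError(
                f"subject {subject}: raw and normalised prediction errors "
                "are collinear (single SD level?)")
        X = np.column_stack([np.ones_like(zd), z(value), zd, zn])
        if np.linalg.cond(X) > 1e8:
            raise CollinearityError(
                f"subject {subject}: ill-conditioned design")
        beta, *_ = np.linalg.lstsq(X, g[response_col].to_numpy(float),
                                   rcond=None)
        rows[subject] = {"coef_raw": float(beta[2]), "coef_norm": float(beta[3])}
    if not rows:
        raise ValueError("no valid trials")
    return NormalizedVsRaw(per_subject=pd.DataFrame.from_dict(rows,
                                                              orient="index"))


def psi_from_nu(nu_by_subject: Mapping[int, float], rng: np.random.Generator,
                jitter: float = 0.15) -> Dict[int, float]:
    """Couple neural adaptation strength to behavioral adaptation weight.

    psi = nu + Gaussian jitter, clipped to [0, 1]: subjects who scale their
    behavioral updates more also code prediction errors more adaptively.
    """
    return {
        int(s): float(np.clip(nu + rng.normal(0.0, jitter), 0.0, 1.0))
        for s, nu in sorted(nu_by_subject.items())
    }
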