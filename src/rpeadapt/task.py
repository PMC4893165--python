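"""Synthetic reward-magnitude prediction task.

The task presents cued conditions in which integer rewards (pounds, 0-100)
are drawn from pseudo-Gaussian distributions with an expected value (EV) of
35 or 65 and a nominal standard deviation (SD) of 5, 10 or 15.  Each of three
sessions alternates two conditions with different SDs in short blocks of four
to six trials; a fixed fraction of trials are unannounced control trials that
differ only in how they pay off.  This module builds such schedules, draws
rewards whose post-truncation moments are calibrated to the nominal EV/SD,
and forward-simulates agent cohorts under any learning rule from
:mod:`rpeadapt.models`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Mapping, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import ModelParams, advance, init_state, SCALE_MIDPOINT

CANONICAL_SDS: Tuple[float, ...] = (5.0, 10.0, 15.0)
CANONICAL_EVS: Tuple[float, ...] = (35.0, 65.0)

#: Documented column order of the trial table (one row per trial).
TRIAL_COLUMNS = (
    "subject", "session", "condition_id", "sd", "ev", "trial_in_condition",
    "prediction", "reward", "rpe", "is_control", "payoff", "missed",
)


class ConfigError(ValueError):
    """Invalid task configuration."""


# ---------------------------------------------------------------------------
# Reward distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardDistribution:
    """Pseudo-Gaussian integer reward distribution on a bounded scale.

    Draws are produced by sampling a Gaussian, rounding to the nearest whole
    pound, and redrawing any value outside ``[lower, upper]``.  Because
    truncation and rounding perturb the moments, the underlying Gaussian's
    location and scale are calibrated numerically (once per condition, then
    cached) so that the *realised* discrete distribution has mean ``mean``
    and standard deviation ``sd`` exactly.

    ``sd = 0`` is a degenerate distribution (every draw equals ``mean``),
    permitted for tests only.
    """

    mean: float
    sd: float
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"sd must be non-negative, got {self.sd!r}")
        if not (self.lower < self.mean < self.upper) and self.sd > 0:
            raise ConfigError(
                f"mean {self.mean!r} must lie strictly inside "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def _calibrated(self) -> Tuple[float, float]:
        return _calibrate_gaussian(self.mean, self.sd, self.lower, self.upper)


def _discrete_moments(mu: float, sigma: float, support: np.ndarray
                      ) -> Tuple[float, float]:
    """Mean and SD of round-then-truncate applied to Normal(mu, sigma)."""
    upper_cdf = stats.norm.cdf((support + 0.5 - mu) / sigma)
    lower_cdf = stats.norm.cdf((support - 0.5 - mu) / sigma)
    p = upper_cdf - lower_cdf
    z = p.sum()
    if z <= 0:
        return math.nan, math.nan
    p = p / z
    m = float(np.dot(support, p))
    v = float(np.dot(support ** 2, p)) - m ** 2
    return m, math.sqrt(max(v, 0.0))


@lru_cache(maxsize=None)
def _calibrate_gaussian(mean: float, sd: float, lower: float, upper: float
                        ) -> Tuple[float, float]:
    """Location/scale of the parent Gaussian that realises the nominal moments."""
    if sd == 0.0:
        return mean, 0.0
    support = np.arange(int(math.ceil(lower)), int(math.floor(upper)) + 1,
                        dtype=float)

    def residual(x: np.ndarray) -> List[float]:
        mu, log_sigma = x
        m, s = _discrete_moments(mu, math.exp(log_sigma), support)
        return [m - mean, s - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr",
                        options={"xtol": 1e-12})
    if not sol.success:  # pragma: no cover - canonical conditions converge
        raise RuntimeError(
            f"moment calibration failed for mean={mean}, sd={sd}: {sol.message}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def draw_rewards(dist: RewardDistribution, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer rewards (vectorised rejection sampling)."""
    if dist.sd == 0.0:
        return np.full(n, round(dist.mean), dtype=np.int64)
    mu, sigma = dist._calibrated
    out = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        draws = np.rint(rng.normal(mu, sigma, size=todo.size))
        ok = (draws >= dist.lower) & (draws <= dist.upper)
        out[todo[ok]] = draws[ok].astype(np.int64)
        todo = todo[~ok]
    return out


def draw_reward(dist: RewardDistribution, rng: np.random.Generator) -> int:
    """Draw a single integer reward in ``[dist.lower, dist.upper]``."""
    if dist.sd == 0.0:
        return round(dist.mean)
    mu, sigma = dist._calibrated
    while True:
        k = round(rng.normal(mu, sigma))
        if dist.lower <= k <= dist.upper:
            return int(k)


# ---------------------------------------------------------------------------
# Task configuration and schedule
# ---------------------------------------------------------------------------

def _reachable_totals(total: int, lo: int, hi: int) -> List[bool]:
    reach = [False] * (total + 1)
    reach[0] = True
    for t in range(1, total + 1):
        reach[t] = any(reach[t - p] for p in range(lo, min(hi, t) + 1))
    return reach


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the synthetic task.

    The canonical task uses 25 trials per condition so that the 20% control
    fraction is exact (5 control trials per condition) while the first 21
    trials of every condition support the early/middle/late phase split.
    Control trials are ordinary learning trials for the agent; only their
    payoff rule differs.
    """

    sds: Tuple[float, ...] = CANONICAL_SDS
    evs: Tuple[float, ...] = CANONICAL_EVS
    session_sd_pairs: Tuple[Tuple[float, float], ...] = (
        (5.0, 10.0), (10.0, 15.0), (5.0, 15.0))
    trials_per_condition: int = 25
    block_range: Tuple[int, int] = (4, 6)
    control_fraction: float = 0.2
    miss_prob: float = 0.0
    reward_lower: float = 0.0
    reward_upper: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.block_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid block range {self.block_range!r}")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        if not _reachable_totals(self.trials_per_condition, lo, hi)[-1]:
            raise ConfigError(
                f"{self.trials_per_condition} trials cannot be partitioned "
                f"into blocks of length {lo}..{hi}"
            )
        if not (0.0 <= self.control_fraction < 1.0):
            raise ConfigError("control_fraction must lie in [0, 1)")
        n_ctrl = self.control_fraction * self.trials_per_condition
        if abs(n_ctrl - round(n_ctrl)) > 1e-9:
            raise ConfigError(
                f"control fraction {self.control_fraction} of "
                f"{self.trials_per_condition} trials per condition is not a "
                "whole number of trials; adjust trials_per_condition"
            )
        if not (0.0 <= self.miss_prob < 1.0):
            raise ConfigError("miss_prob must lie in [0, 1)")
        counts: Dict[float, int] = {}
        for pair in self.session_sd_pairs:
            a, b = pair
            if a == b:
                raise ConfigError("a session must pair two different SDs")
            for sd in pair:
                if sd not in self.sds:
                    raise ConfigError(f"session SD {sd!r} not in sds {self.sds}")
                counts[sd] = counts.get(sd, 0) + 1
        for sd in self.sds:
            if counts.get(sd, 0) != len(self.evs):
                raise ConfigError(
                    f"SD {sd} appears {counts.get(sd, 0)} times across "
                    f"sessions but must appear once per EV ({len(self.evs)})"
                )

    @property
    def n_controls_per_condition(self) -> int:
        return round(self.control_fraction * self.trials_per_condition)


class ConditionSpec(NamedTuple):
    condition_id: str
    session: int
    sd: float
    ev: float


class ScheduledTrial(NamedTuple):
    session: int
    condition_id: str
    sd: float
    ev: float
    trial_in_condition: int
    is_control: bool


@dataclass(frozen=True)
class TaskSchedule:
    """Fully resolved presentation order for one subject."""

    config: TaskConfig
    conditions: Tuple[ConditionSpec, ...]
    blocks: Tuple[Tuple[Tuple[str, int], ...], ...]  # per session: (cid, length)
    control_trials: Mapping[str, frozenset]

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * self.config.trials_per_condition

    def condition(self, condition_id: str) -> ConditionSpec:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def trial_sequence(self) -> Iterator[ScheduledTrial]:
        """Trials in presentation order."""
        counters = {c.condition_id: 0 for c in self.conditions}
        specs = {c.condition_id: c for c in self.conditions}
        for session_blocks in self.blocks:
            for cid, length in session_blocks:
                spec = specs[cid]
                ctrl = self.control_trials[cid]
                for _ in range(length):
                    counters[cid] += 1
                    t = counters[cid]
                    yield ScheduledTrial(spec.session, cid, spec.sd, spec.ev,
                                         t, t in ctrl)


def _sample_composition(total: int, lo: int, hi: int,
                        rng: np.random.Generator) -> List[int]:
    reach = _reachable_totals(total, lo, hi)
    parts: List[int] = []
    rem = total
    while rem > 0:
        feasible = [p for p in range(lo, min(hi, rem) + 1) if reach[rem - p]]
        parts.append(int(rng.choice(feasible)))
        rem -= parts[-1]
    return parts


def build_schedule(config: TaskConfig, rng: np.random.Generator) -> TaskSchedule:
    """Build a randomised schedule satisfying all task invariants.

    Session order and the assignment of EVs to each SD's two occurrences are
    randomised per call (per subject); block lengths are drawn uniformly over
    valid partitions; control trials are placed uniformly at random within
    each condition, exactly ``control_fraction`` of its trials.
    Deterministic given the generator's state.
    """
    order = rng.permutation(len(config.session_sd_pairs))
    ordered_pairs = [config.session_sd_pairs[i] for i in order]

    occurrences: Dict[float, List[int]] = {}
    for s, pair in enumerate(ordered_pairs):
        for sd in pair:
            occurrences.setdefault(sd, []).append(s)
    ev_of: Dict[Tuple[int, float], float] = {}
    for sd in sorted(occurrences):
        evs = [config.evs[i] for i in rng.permutation(len(config.evs))]
        for s, ev in zip(occurrences[sd], evs):
            ev_of[(s, sd)] = ev

    conditions: List[ConditionSpec] = []
    for s, pair in enumerate(ordered_pairs):
        for sd in pair:
            ev = ev_of[(s, sd)]
            cid = f"s{s + 1}_sd{sd:g}_ev{ev:g}"
            conditions.append(ConditionSpec(cid, s + 1, sd, ev))

    lo, hi = config.block_range
    T = config.trials_per_condition
    session_blocks: List[Tuple[Tuple[str, int], ...]] = []
    for s, pair in enumerate(ordered_pairs):
        cids = [f"s{s + 1}_sd{sd:g}_ev{ev_of[(s, sd)]:g}" for sd in pair]
        for _ in range(1000):
            comps = [_sample_composition(T, lo, hi, rng) for _ in cids]
            if abs(len(comps[0]) - len(comps[1])) <= 1:
                break
        else:  # pragma: no cover - canonical ranges always succeed
            raise ConfigError(
                "could not interleave the two conditions in alternating blocks"
            )
        if len(comps[0]) > len(comps[1]):
            first = 0
        elif len(comps[1]) > len(comps[0]):
            first = 1
        else:
            first = int(rng.integers(2))
        blocks: List[Tuple[str, int]] = []
        idx = [0, 0]
        turn = first
        while idx[0] < len(comps[0]) or idx[1] < len(comps[1]):
            if idx[turn] < len(comps[turn]):
                blocks.append((cids[turn], comps[turn][idx[turn]]))
                idx[turn] += 1
            turn = 1 - turn
        session_blocks.append(tuple(blocks))

    n_ctrl = config.n_controls_per_condition
    control_trials = {
        c.condition_id: frozenset(
            (rng.choice(T, size=n_ctrl, replace=False) + 1).tolist()
        ) if n_ctrl else frozenset()
        for c in conditions
    }

    return TaskSchedule(config=config, conditions=tuple(conditions),
                        blocks=tuple(session_blocks),
                        control_trials=control_trials)


# ---------------------------------------------------------------------------
# Agent simulation
# ---------------------------------------------------------------------------

def default_control_payoff(abs_error: float, sd: float) -> float:
    """Control-trial payoff: performance-based, scaled by the condition SD.

    A unitless default: full payoff (10) for a perfect prediction, declining
    by one unit per SD-worth of error, floored at zero.
    """
    return max(0.0, 10.0 - abs_error / sd)


def simulate_agent(model: str, params: ModelParams, schedule: TaskSchedule,
                   rng: np.random.Generator, subject_id: int = 0,
                   y0: Optional[float] = None,
                   control_payoff: Callable[[float, float], float] = default_control_payoff,
                   ) -> pd.DataFrame:
    """Forward-simulate one agent over a schedule.

    The agent's internal prediction follows the model's own recursive update;
    the *emitted* prediction adds Gaussian observation noise with variance
    ``params.sigma_hat_sq`` and is clipped to the prediction scale, and the
    recursion then conditions on the emitted value (so the generative process
    matches the one-step-ahead likelihood used for fitting).  Missed trials
    occur with the configured probability; the state then advances on the
    reward alone.  Fully reproducible given the generator's state.
    """
    cfg = schedule.config
    dists = {
        c.condition_id: RewardDistribution(c.ev, c.sd, cfg.reward_lower,
                                           cfg.reward_upper)
        for c in schedule.conditions
    }
    states = {c.condition_id: init_state(model, params, y0=y0)
              for c in schedule.conditions}
    noise_sd = math.sqrt(params.sigma_hat_sq)

    rows = []
    for t in schedule.trial_sequence():
        reward = draw_reward(dists[t.condition_id], rng)
        missed = bool(rng.random() < cfg.miss_prob) if cfg.miss_prob > 0 else False
        state = states[t.condition_id]
        if missed:
            prediction = math.nan
            rpe = math.nan
            payoff = 0.0
            y_use = state.y
        else:
            prediction = state.y + rng.normal(0.0, noise_sd)
            prediction = min(cfg.reward_upper, max(cfg.reward_lower, prediction))
            rpe = reward - prediction
            y_use = prediction
            if t.is_control:
                payoff = control_payoff(abs(prediction - t.ev), t.sd)
            else:
                payoff = reward / 10.0
        states[t.condition_id] = advance(model, params, state, y_use,
                                         float(reward), sd=t.sd)
        rows.append((subject_id, t.session, t.condition_id, t.sd, t.ev,
                     t.trial_in_condition, prediction, float(reward), rpe,
                     t.is_control, payoff, missed))

    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def cohort_param_sampler(model: str,
                         alpha_range: Tuple[float, float] = (0.1, 0.9),
                         gamma_range: Tuple[float, float] = (0.2, 0.8),
                         nu_range: Tuple[float, float] = (0.0, 1.0),
                         C: float = 0.05,
                         sigma_hat_sq: float = 25.0,
                         dual_offset: float = 0.2,
                         ) -> Callable[[np.random.Generator], ModelParams]:
    """Per-subject true-parameter sampler for cohort simulations.

    Simulation presets: ``C`` fixed at 0.05 gain per pound of |RPE| and a
    reported-prediction noise variance of 25 (SD 5 pounds on a 0-100 scale).
    The Bayesian sampler assumes the true per-condition reward variances
    (``sd**2``).  For the dual-rate RW, ``alpha_neg = alpha_pos +
    dual_offset`` (clipped to 1).
    """
    def sampler(rng: np.random.Generator) -> ModelParams:
        if model == "rw":
            return ModelParams(alpha=float(rng.uniform(*alpha_range)),
                               sigma_hat_sq=sigma_hat_sq)
        if model == "rw_dual":
            ap = float(rng.uniform(*alpha_range))
            return ModelParams(alpha_pos=ap,
                               alpha_neg=min(1.0, ap + dual_offset),
                               sigma_hat_sq=sigma_hat_sq)
        if model == "ph":
            return ModelParams(alpha=float(rng.uniform(*alpha_range)),
                               gamma=float(rng.uniform(*gamma_range)),
                               C=C, sigma_hat_sq=sigma_hat_sq)
        if model == "aph":
            return ModelParams(alpha=float(rng.uniform(*alpha_range)),
                               gamma=float(rng.uniform(*gamma_range)),
                               C=C, nu=float(rng.uniform(*nu_range)),
                               sigma_hat_sq=sigma_hat_sq)
        if model == "bayes":
            return ModelParams(prior_var=400.0,
                               reward_var={5.0: 25.0, 10.0: 100.0, 15.0: 225.0},
                               sigma_hat_sq=sigma_hat_sq)
        raise ValueError(f"unknown model {model!r}")

    return sampler


def simulate_cohort(n_subjects: int, model: str,
                    param_sampler: Callable[[np.random.Generator], ModelParams],
                    config: TaskConfig, rng: np.random.Generator,
                    start_subject: int = 0,
                    ) -> Tuple[pd.DataFrame, Dict[int, ModelParams]]:
    """Simulate a cohort; returns the concatenated trial table and the truth.

    Each subject gets an independent child generator (spawned in subject
    order), their own randomised schedule, and true parameters drawn from
    ``param_sampler``; the true parameters are returned keyed by subject for
    recovery analyses.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    frames = []
    truth: Dict[int, ModelParams] = {}
    for i in range(n_subjects):
        sub = start_subject + i
        sub_rng = rng.spawn(1)[0]
        params = param_sampler(sub_rng)
        schedule = build_schedule(config, sub_rng)
        frames.append(simulate_agent(model, params, schedule, sub_rng,
                                     subject_id=sub))
        truth[sub] = params
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Trial-table I/O
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial table as CSV in the documented column order."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    df["missed"] = df["missed"].astype(bool)
    return df[list(TRIAL_COLUMNS)]


def write_truth(truth: Mapping[int, ModelParams], path: Union[str, Path]) -> None:
    """Write cohort true parameters as a JSON sidecar."""
    payload = {}
    for subject, params in truth.items():
        d = asdict(params)
        if isinstance(d["reward_var"], Mapping):
            d["reward_var"] = {f"{k:g}": v for k, v in d["reward_var"].items()}
        payload[str(subject)] = d
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: Union[str, Path]) -> Dict[int, Dict[str, float]]:
    """Read a truth sidecar; values returned as plain dictionaries."""
    payload = json.loads(Path(path).read_text())
    return {int(s): d for s, d in payload.items()}
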