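"""Trial-by-trial learning rules for reward-magnitude prediction.

An agent (or participant) predicts the magnitude ``y`` of an upcoming reward
``r`` drawn from a cued distribution with expected value EV and standard
deviation SD.  Every rule implemented here shares the error-driven update

    y[n+1] = y[n] + k[n] * delta[n],        delta[n] = r[n] - y[n],

where ``k[n]`` is the gain (learning rate, also called Kalman gain) and
``delta[n]`` is the reward prediction error (RPE) on trial ``n``.  The rules
differ only in how the gain is computed:

``bayes``
    Conjugate-Gaussian mean tracker.  The gain is the Kalman gain
    ``post_var / (post_var + reward_var)`` and the posterior variance shrinks
    on every observation, so updates become asymptotically small.
``rw``
    Rescorla-Wagner: constant gain ``k[n] = alpha``.
``rw_dual``
    Rescorla-Wagner with separate gains for positive (``alpha_pos``) and
    negative (``alpha_neg``) prediction errors.
``ph``
    Pearce-Hall associability: ``k[n+1] = gamma*C*|delta[n]| + (1-gamma)*k[n]``
    initialised at ``k[0] = alpha``.  The gain tracks recent unsigned RPEs
    with exponential decay ``gamma``; ``C`` converts pounds of RPE into gain.
``aph``
    Adaptive Pearce-Hall: the PH rule with the prediction error divisively
    scaled by ``omega = (1 - nu) + nu * log(SD) / D``.  Updates are compressed
    more when reward variability is larger; ``nu`` in [0, 1] is the
    per-subject adaptation weight.  With ``D = log(smallest SD)`` the scaling
    is anchored so that ``omega = 1`` for the narrowest distribution.

All functions are pure: they take and return immutable state, so the same
code drives both forward simulation and one-step-ahead likelihood evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Tuple, Union

MODEL_IDS = ("bayes", "rw", "rw_dual", "ph", "aph")

#: Default divisive-scaling normaliser: anchors omega = 1 at SD = 5, the
#: narrowest canonical distribution, so nu interpolates between "no scaling"
#: and "full log-SD scaling relative to the narrowest condition".
DEFAULT_D = math.log(5.0)

#: Midpoint of the 0-100 pound prediction scale; default initial prediction.
SCALE_MIDPOINT = 50.0


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not (value > 0.0):
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector shared by all models.

    Parameters irrelevant to a given model are simply ignored by that model's
    update; fitting declares its own free subset explicitly (see
    :mod:`rpeadapt.fitting`), so nothing is silently defaulted there.

    Attributes
    ----------
    alpha:
        Constant learning rate (``rw``) or initial gain ``k[0]`` (``ph``,
        ``aph``), in [0, 1].
    gamma:
        Pearce-Hall decay constant in [0, 1].
    C:
        Pearce-Hall scaling coefficient (> 0), gain per pound of |RPE|.
    nu:
        Adaptation weight in [0, 1] (``aph`` only).
    D:
        Divisive-scaling normaliser (> 0); fixed, not fitted.
    sigma_hat_sq:
        Observation-noise variance of reported predictions around the model's
        one-step prediction (the likelihood's Gaussian variance), > 0.
    alpha_pos, alpha_neg:
        Learning rates for positive / negative RPEs (``rw_dual``), in [0, 1].
    prior_mean:
        Bayesian prior mean of the tracked EV (pounds).
    prior_var:
        Bayesian prior variance (> 0).
    reward_var:
        Assumed reward variance sigma^2 (> 0) for the Bayesian tracker;
        either a scalar or a mapping from condition SD to variance (the
        Bayesian model carries one variance per SD condition).
    """

    alpha: float = 0.3
    gamma: float = 0.5
    C: float = 0.05
    nu: float = 0.0
    D: float = DEFAULT_D
    sigma_hat_sq: float = 25.0
    alpha_pos: float = 0.3
    alpha_neg: float = 0.3
    prior_mean: float = SCALE_MIDPOINT
    prior_var: float = 400.0
    reward_var: Union[float, Mapping[float, float]] = 100.0

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "nu", "alpha_pos", "alpha_neg"):
            _check_unit(name, getattr(self, name))
        for name in ("C", "D", "sigma_hat_sq", "prior_var"):
            _check_positive(name, getattr(self, name))
        if isinstance(self.reward_var, Mapping):
            for sd, var in self.reward_var.items():
                _check_positive(f"reward_var[{sd}]", var)
        else:
            _check_positive("reward_var", self.reward_var)

    def reward_variance(self, sd: float) -> float:
        """Assumed reward variance for a condition with standard deviation ``sd``."""
        if isinstance(self.reward_var, Mapping):
            try:
                return self.reward_var[sd]
            except KeyError:
                raise KeyError(f"no reward variance configured for SD {sd!r}")
        return self.reward_var


@dataclass(frozen=True)
class LearnerState:
    """Recursive learner state carried between trials.

    ``y`` is the prediction the model would make on the upcoming trial,
    ``k`` the gain that will be applied to the upcoming RPE (PH family),
    ``post_var`` the current Bayesian posterior variance, and ``trial`` the
    1-based index of the upcoming trial within its condition.
    """

    y: float
    k: float = 0.0
    post_var: float = 400.0
    trial: int = 1


def omega(sd: float, nu: float, D: float = DEFAULT_D) -> float:
    """Divisive RPE scaling factor ``(1 - nu) + nu * log(sd) / D``.

    Monotone increasing in ``sd`` for ``nu > 0``, so the effective update
    ``k * delta / omega`` is non-increasing in SD for fixed ``k`` and
    ``delta``.
    """
    if sd <= 0.0:
        raise ValueError(f"sd must be positive, got {sd!r}")
    _check_unit("nu", nu)
    _check_positive("D", D)
    w = (1.0 - nu) + nu * math.log(sd) / D
    if w <= 0.0:
        raise ValueError(
            f"omega = {w!r} <= 0 for sd={sd}, nu={nu}, D={D}; "
            "D must be at least log(smallest SD)"
        )
    return w


def bayes_gain(post_var: float, reward_var: float) -> Tuple[float, float]:
    """Kalman gain and updated posterior variance of the Gaussian mean tracker.

    Returns ``(gain, new_post_var)`` with
    ``gain = post_var / (post_var + reward_var)`` in (0, 1) and
    ``new_post_var = post_var * reward_var / (post_var + reward_var)``,
    which is strictly smaller than ``post_var``.
    """
    _check_positive("post_var", post_var)
    _check_positive("reward_var", reward_var)
    total = post_var + reward_var
    return post_var / total, post_var * reward_var / total


def rw_gain(params: ModelParams) -> float:
    """Constant Rescorla-Wagner gain ``alpha``."""
    return params.alpha


def rw_dual_gain(delta: float, params: ModelParams) -> float:
    """Sign-dependent Rescorla-Wagner gain.

    A zero RPE is assigned to the positive branch (a measure-zero event for
    continuous rewards; the assignment is arbitrary but fixed).
    """
    return params.alpha_pos if delta >= 0.0 else params.alpha_neg


def ph_gain(k_prev: float, prev_abs_rpe: float, params: ModelParams,
            w: float = 1.0) -> float:
    """Pearce-Hall associability update, clipped to [0, 1].

    ``gamma*C*|delta|/w + (1-gamma)*k_prev``.  The raw recursion can exceed 1
    for large unsigned RPEs, which produces oscillatory divergence on a
    bounded prediction scale; clipping to the unit interval is the minimal
    stabilisation.
    """
    if prev_abs_rpe < 0.0:
        raise ValueError("prev_abs_rpe must be non-negative")
    g = params.gamma * params.C * prev_abs_rpe / w + (1.0 - params.gamma) * k_prev
    return min(1.0, max(0.0, g))


def init_state(model: str, params: ModelParams,
               y0: Optional[float] = None) -> LearnerState:
    """Initial learner state before the first trial of a condition.

    ``y0`` defaults to the prior mean for the Bayesian tracker and to the
    scale midpoint (50) otherwise.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_IDS}")
    if y0 is None:
        y0 = params.prior_mean if model == "bayes" else SCALE_MIDPOINT
    k0 = params.alpha if model in ("rw", "ph", "aph") else 0.0
    return LearnerState(y=float(y0), k=float(k0),
                        post_var=float(params.prior_var), trial=1)


def advance(model: str, params: ModelParams, state: LearnerState,
            y_obs: float, reward: float, sd: Optional[float] = None) -> LearnerState:
    """Advance the learner one trial, conditioning on the observed prediction.

    ``y_obs`` is the prediction actually made on the current trial (the
    participant's reported value when fitting, the agent's emitted value when
    simulating) and ``reward`` the reward received, so
    ``delta = reward - y_obs``.  The returned state's ``y`` is the model's
    prediction for the next trial (the one-step-ahead mean mu of the
    likelihood).  ``sd`` is required by the ``aph`` and ``bayes`` rules.
    """
    delta = reward - y_obs
    post_var = state.post_var

    if model == "rw":
        k_apply = params.alpha
        y_next = y_obs + k_apply * delta
        k_next = k_apply
    elif model == "rw_dual":
        k_apply = rw_dual_gain(delta, params)
        y_next = y_obs + k_apply * delta
        k_next = k_apply
    elif model == "ph":
        k_apply = state.k
        y_next = y_obs + k_apply * delta
        k_next = ph_gain(k_apply, abs(delta), params)
    elif model == "aph":
        if sd is None:
            raise ValueError("the adaptive PH rule requires the condition SD")
        w = omega(sd, params.nu, params.D)
        k_apply = state.k
        y_next = y_obs + k_apply * delta / w
        k_next = ph_gain(k_apply, abs(delta), params, w=w)
    elif model == "bayes":
        if sd is None:
            raise ValueError("the Bayesian tracker requires the condition SD")
        k_apply, post_var = bayes_gain(state.post_var, params.reward_variance(sd))
        y_next = y_obs + k_apply * delta
        k_next = k_apply
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_IDS}")

    return LearnerState(y=y_next, k=k_next, post_var=post_var,
                        trial=state.trial + 1)


def one_step_prediction(model: str, params: ModelParams, state: LearnerState,
                        y_obs: Optional[float], reward: float,
                        sd: Optional[float] = None
                        ) -> Tuple[float, LearnerState]:
    """One-step-ahead predicted mean mu and the advanced carried state.

    When fitting, the RPE is computed from the participant's *observed*
    prediction on the current trial, and ``mu`` is the model's prediction for
    the next trial.  On a missed trial (``y_obs`` is None) the state advances
    on the reward alone, substituting the model's own prediction; the caller
    excludes such trials from the likelihood.
    """
    if y_obs is None:
        y_obs = state.y
    new_state = advance(model, params, state, y_obs, reward, sd=sd)
    return new_state.y, new_state


def adaptive_ph_step(state: LearnerState, reward: float, sd: float,
                     params: ModelParams) -> Tuple[float, float]:
    """Self-generated adaptive-PH step: returns ``(new_y, new_k)``.

    Convenience wrapper that computes the RPE from the state's own current
    prediction (forward simulation, no observed prediction).
    """
    new = advance("aph", params, state, state.y, reward, sd=sd)
    return new.y, new.k


def rw_dual_step(state: LearnerState, reward: float,
                 params: ModelParams) -> Tuple[float, float]:
    """Self-generated dual-rate RW step: returns ``(new_y, gain_used)``."""
    delta = reward - state.y
    g = rw_dual_gain(delta, params)
    return state.y + g * delta, g
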