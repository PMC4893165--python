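"""Maximum-likelihood fitting and model comparison.

Each model is fitted per subject by maximising the likelihood of the
subject's reported prediction sequence Y under a Gaussian observation model,
p(y_m | Phi) = N(mu_m, sigma_hat^2), where mu_m is the model's one-step-ahead
prediction conditioned on the *observed* previous predictions and rewards
(the standard identifiable choice for recursive learning rules).  Parameters
are shared across conditions; the learner's recursive state resets at the
start of each condition, which has its own cue and reward stream.

Fitting uses bounded multi-start local optimisation (L-BFGS-B); the
observation-noise variance sigma_hat^2 is profiled out analytically at every
objective evaluation (its conditional MLE is the mean squared residual,
clamped to its bounds), which removes one dimension from the search without
changing the maximum.  Models are compared per subject via AIC/BIC and, for
nested pairs, a fixed-effects likelihood-ratio test that sums the
per-subject log-likelihood improvements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import DEFAULT_D, MODEL_IDS, ModelParams, SCALE_MIDPOINT

#: Bounds of the free parameters.  C is bounded away from zero and above by
#: 0.2 because it is not identifiable jointly with gamma at the extremes.
PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "C": (1e-6, 0.2),
    "nu": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "prior_var": (1e-3, 1e4),
    "reward_var": (1e-3, 1e4),
}
SIGMA_HAT_SQ_BOUNDS = (1e-3, 1e3)

#: (restricted, full) pairs for which the likelihood-ratio test is valid.
NESTED_PAIRS = {("rw", "ph"), ("rw", "aph"), ("ph", "aph"), ("rw", "rw_dual")}

_LOG_2PI = math.log(2.0 * math.pi)


class _Cond(NamedTuple):
    sd: float
    group: object           # grouping key for per-group learning rates
    y: Tuple[float, ...]    # observed predictions (nan when missed)
    r: Tuple[float, ...]
    missed: Tuple[bool, ...]


def _prepare(trials: pd.DataFrame, group_col: Optional[str] = None
             ) -> List[_Cond]:
    """Split one subject's trial table into per-condition arrays."""
    if trials.empty:
        raise ValueError("empty trial set")
    if trials["subject"].nunique() > 1:
        raise ValueError("fit_subject expects trials from a single subject")
    conds: List[_Cond] = []
    ordered = trials.sort_values(["session", "condition_id", "trial_in_condition"])
    for (_, cid), g in ordered.groupby(["session", "condition_id"], sort=True):
        sd = float(g["sd"].iloc[0])
        group = g[group_col].iloc[0] if group_col else None
        conds.append(_Cond(
            sd=sd, group=group,
            y=tuple(float(v) for v in g["prediction"]),
            r=tuple(float(v) for v in g["reward"]),
            missed=tuple(bool(v) for v in g["missed"]),
        ))
    if not any(not m for c in conds for m in c.missed):
        raise ValueError("no non-missed trials to fit")
    return conds


# ---------------------------------------------------------------------------
# Residual recursions (python loops; hot path of every fit)
# ---------------------------------------------------------------------------

def _resid_rw(alpha: float, conds: Sequence[_Cond], y0: float) -> List[float]:
    out: List[float] = []
    app = out.append
    for c in conds:
        mu = y0
        for y, r, m in zip(c.y, c.r, c.missed):
            if m:
                yu = mu
            else:
                app(y - mu)
                yu = y
            mu = yu + alpha * (r - yu)
    return out


def _resid_rw_dual(alpha_pos: float, alpha_neg: float,
                   conds: Sequence[_Cond], y0: float) -> List[float]:
    out: List[float] = []
    app = out.append
    for c in conds:
        mu = y0
        for y, r, m in zip(c.y, c.r, c.missed):
            if m:
                yu = mu
            else:
                app(y - mu)
                yu = y
            d = r - yu
            a = alpha_pos if d >= 0.0 else alpha_neg
            mu = yu + a * d
    return out


def _resid_ph(alpha_of_group, gamma: float, C: float, nu: float, D: float,
              conds: Sequence[_Cond], y0: float) -> List[float]:
    """Shared PH/adaptive-PH recursion; plain PH is nu = 0.

    ``alpha_of_group`` maps a condition's group key to its initial gain,
    supporting per-SD (or per-condition) learning-rate refits.
    """
    out: List[float] = []
    app = out.append
    keep = 1.0 - gamma
    gC = gamma * C
    for c in conds:
        if nu == 0.0:
            w = 1.0
        else:
            w = (1.0 - nu) + nu * math.log(c.sd) / D
            if w <= 0.0:
                raise ValueError(f"omega <= 0 for sd={c.sd}, nu={nu}, D={D}")
        k = alpha_of_group(c.group)
        mu = y0
        for y, r, m in zip(c.y, c.r, c.missed):
            if m:
                yu = mu
            else:
                app(y - mu)
                yu = y
            d = r - yu
            mu = yu + k * d / w
            k = gC * (d if d >= 0.0 else -d) / w + keep * k
            if k > 1.0:
                k = 1.0
            elif k < 0.0:
                k = 0.0
    return out


def _resid_bayes(prior_var: float, reward_var_of_sd: Mapping[float, float],
                 conds: Sequence[_Cond], y0: float) -> List[float]:
    out: List[float] = []
    app = out.append
    for c in conds:
        rv = reward_var_of_sd[c.sd]
        pv = prior_var
        mu = y0
        for y, r, m in zip(c.y, c.r, c.missed):
            if m:
                yu = mu
            else:
                app(y - mu)
                yu = y
            k = pv / (pv + rv)
            mu = yu + k * (r - yu)
            pv = pv * rv / (pv + rv)
    return out


def _residuals(model: str, p: Mapping[str, float], conds: Sequence[_Cond],
               y0: float) -> List[float]:
    if model == "rw":
        return _resid_rw(p["alpha"], conds, y0)
    if model == "rw_dual":
        return _resid_rw_dual(p["alpha_pos"], p["alpha_neg"], conds, y0)
    if model == "ph":
        a = p["alpha"]
        return _resid_ph(lambda _g: a, p["gamma"], p["C"], 0.0, DEFAULT_D,
                         conds, y0)
    if model == "aph":
        a = p["alpha"]
        return _resid_ph(lambda _g: a, p["gamma"], p["C"], p["nu"],
                         p.get("D", DEFAULT_D), conds, y0)
    if model == "bayes":
        rv = {sd: p[f"reward_var[{sd:g}]"] for sd in {c.sd for c in conds}}
        return _resid_bayes(p["prior_var"], rv, conds, y0)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_IDS}")


def free_param_names(model: str, sds: Iterable[float] = ()) -> Tuple[str, ...]:
    """Free parameters optimised for each model (sigma_hat_sq is profiled).

    The Bayesian tracker carries one reward variance per SD condition, so its
    free set depends on the SDs present in the data.
    """
    if model == "rw":
        return ("alpha",)
    if model == "rw_dual":
        return ("alpha_pos", "alpha_neg")
    if model == "ph":
        return ("alpha", "gamma", "C")
    if model == "aph":
        return ("alpha", "gamma", "C", "nu")
    if model == "bayes":
        return ("prior_var",) + tuple(
            f"reward_var[{sd:g}]" for sd in sorted(set(sds)))
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_IDS}")


def _bound_of(name: str) -> Tuple[float, float]:
    return PARAM_BOUNDS["reward_var" if name.startswith("reward_var") else name]


def _nll_from_residuals(resid: Sequence[float], sigma_sq: float) -> float:
    m = len(resid)
    ss = sum(r * r for r in resid)
    return 0.5 * m * (_LOG_2PI + math.log(sigma_sq)) + ss / (2.0 * sigma_sq)


def _profiled_nll(resid: Sequence[float]) -> Tuple[float, float]:
    m = len(resid)
    ss = sum(r * r for r in resid)
    s2 = min(max(ss / m, SIGMA_HAT_SQ_BOUNDS[0]), SIGMA_HAT_SQ_BOUNDS[1])
    return 0.5 * m * (_LOG_2PI + math.log(s2)) + ss / (2.0 * s2), s2


def negative_log_likelihood(model: str, params: ModelParams,
                            trials: pd.DataFrame,
                            y0: float = SCALE_MIDPOINT) -> float:
    """Negative log-likelihood of one subject's predictions under a model.

    Sums -log N(y_m; mu_m, sigma_hat^2) over all non-missed trials of all
    conditions, with the recursive state reset at each condition start.  The
    first trial of a condition is evaluated against the initial prediction
    ``y0`` (scale midpoint by default; the Bayesian prior mean coincides with
    it).  Missed trials are excluded from the sum but advance the state on
    the reward alone.
    """
    conds = _prepare(trials)
    p = {
        "alpha": params.alpha, "gamma": params.gamma, "C": params.C,
        "nu": params.nu, "D": params.D,
        "alpha_pos": params.alpha_pos, "alpha_neg": params.alpha_neg,
        "prior_var": params.prior_var,
    }
    for sd in {c.sd for c in conds}:
        p[f"reward_var[{sd:g}]"] = params.reward_variance(sd)
    resid = _residuals(model, p, conds,
                       params.prior_mean if model == "bayes" else y0)
    for r in resid:
        if not math.isfinite(r):
            raise ValueError("non-finite model prediction in likelihood")
    return _nll_from_residuals(resid, params.sigma_hat_sq)


# ---------------------------------------------------------------------------
# Per-subject fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts maximum-likelihood fit of one model to one subject."""

    model: str
    params: ModelParams
    free_names: Tuple[str, ...]
    loglik: float
    n_obs: int
    n_free: int
    aic: float
    bic: float
    n_restarts: int
    converged: bool
    best_restart: int

    def to_dict(self) -> Dict[str, object]:
        p = {name: _get_param(self.params, name) for name in self.free_names}
        p["sigma_hat_sq"] = self.params.sigma_hat_sq
        return {
            "model": self.model, "params": p, "loglik": self.loglik,
            "n_obs": self.n_obs, "n_free": self.n_free, "aic": self.aic,
            "bic": self.bic, "n_restarts": self.n_restarts,
            "converged": self.converged, "best_restart": self.best_restart,
        }


def _get_param(params: ModelParams, name: str) -> float:
    if name.startswith("reward_var["):
        sd = float(name[len("reward_var["):-1])
        return params.reward_variance(sd)
    return getattr(params, name)


def _params_from_vector(model: str, names: Sequence[str], x: Sequence[float],
                        sigma_hat_sq: float) -> ModelParams:
    kw: Dict[str, object] = {"sigma_hat_sq": sigma_hat_sq}
    reward_var: Dict[float, float] = {}
    for name, value in zip(names, x):
        if name.startswith("reward_var["):
            reward_var[float(name[len("reward_var["):-1])] = float(value)
        else:
            kw[name] = float(value)
    if reward_var:
        kw["reward_var"] = reward_var
    return ModelParams(**kw)


def _sample_start(names: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    x = np.empty(len(names))
    for i, name in enumerate(names):
        lo, hi = _bound_of(name)
        if name.startswith(("prior_var", "reward_var")):
            x[i] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            x[i] = rng.uniform(lo, hi)
    return x


def fit_subject(model: str, trials: pd.DataFrame, restarts: int = 10,
                rng: Optional[np.random.Generator] = None,
                y0: float = SCALE_MIDPOINT,
                warm_starts: Sequence[Mapping[str, float]] = (),
                tol: float = 1e-6) -> FitResult:
    """Fit one model to one subject's trials by multi-start bounded MLE.

    ``restarts`` random starting points are drawn uniformly within bounds
    (log-uniformly for variance-like parameters); any ``warm_starts`` (name ->
    value mappings, e.g. a nested model's solution) are tried first.  The
    best negative log-likelihood across all starts is retained, so the NLL is
    weakly decreasing in the number of restarts for a fixed generator seed.
    Deterministic given the generator's state.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    conds = _prepare(trials)
    names = free_param_names(model, sds=[c.sd for c in conds])
    bounds = [_bound_of(n) for n in names]
    use_y0 = y0

    def objective(x: np.ndarray) -> float:
        p = dict(zip(names, x))
        resid = _residuals(model, p, conds, use_y0)
        return _profiled_nll(resid)[0]

    starts: List[np.ndarray] = []
    for w in warm_starts:
        starts.append(np.array([
            min(max(w[n], _bound_of(n)[0]), _bound_of(n)[1]) for n in names
        ]))
    starts.extend(_sample_start(names, rng) for _ in range(restarts))
    if not starts:
        raise ValueError("need at least one start (restarts >= 1)")

    best_fun = math.inf
    best_x: Optional[np.ndarray] = None
    best_idx = -1
    best_ok = False
    for i, x0 in enumerate(starts):
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": tol, "maxiter": 500})
        if res.fun < best_fun:
            best_fun, best_x, best_idx, best_ok = float(res.fun), res.x, i, bool(res.success)

    if best_x is None or not math.isfinite(best_fun):  # pragma: no cover
        raise RuntimeError(f"all {len(starts)} restarts failed for {model}")

    resid = _residuals(model, dict(zip(names, best_x)), conds, use_y0)
    nll, sigma_sq = _profiled_nll(resid)
    params = _params_from_vector(model, names, best_x, sigma_sq)
    n_free = len(names) + 1  # + sigma_hat_sq
    n_obs = len(resid)
    loglik = -nll
    return FitResult(
        model=model, params=params, free_names=names, loglik=loglik,
        n_obs=n_obs, n_free=n_free,
        aic=2.0 * n_free - 2.0 * loglik,
        bic=n_free * math.log(n_obs) - 2.0 * loglik,
        n_restarts=len(starts), converged=best_ok, best_restart=best_idx,
    )


def fit_subject_models(trials: pd.DataFrame,
                       models: Sequence[str] = ("bayes", "rw", "ph", "aph"),
                       restarts: int = 10,
                       rng: Optional[np.random.Generator] = None,
                       y0: float = SCALE_MIDPOINT) -> Dict[str, FitResult]:
    """Fit several models to one subject, warm-starting nested pairs.

    The RW solution seeds the PH and dual-rate fits, and the PH solution
    (with nu = 0) seeds the adaptive-PH fit, which guarantees that each full
    model's log-likelihood is at least its nested restriction's up to
    optimiser tolerance.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out: Dict[str, FitResult] = {}
    for model in models:
        warm: List[Mapping[str, float]] = []
        if model == "ph" and "rw" in out:
            warm.append({"alpha": out["rw"].params.alpha, "gamma": 0.0,
                         "C": 0.05})
        elif model == "aph" and "ph" in out:
            ph = out["ph"].params
            warm.append({"alpha": ph.alpha, "gamma": ph.gamma, "C": ph.C,
                         "nu": 0.0})
        elif model == "rw_dual" and "rw" in out:
            warm.append({"alpha_pos": out["rw"].params.alpha,
                         "alpha_neg": out["rw"].params.alpha})
        out[model] = fit_subject(model, trials, restarts=restarts,
                                 rng=rng.spawn(1)[0], y0=y0, warm_starts=warm)
    return out


def fit_cohort(trials: pd.DataFrame,
               models: Sequence[str] = ("bayes", "rw", "ph", "aph"),
               restarts: int = 10,
               rng: Optional[np.random.Generator] = None,
               y0: float = SCALE_MIDPOINT) -> Dict[int, Dict[str, FitResult]]:
    """Fit every model to every subject; returns fits[subject][model]."""
    if rng is None:
        rng = np.random.default_rng(0)
    fits: Dict[int, Dict[str, FitResult]] = {}
    for subject in sorted(trials["subject"].unique()):
        sub_rng = rng.spawn(1)[0]
        fits[int(subject)] = fit_subject_models(
            trials[trials["subject"] == subject], models=models,
            restarts=restarts, rng=sub_rng, y0=y0)
    return fits


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

_MODEL_ORDER = ("bayes", "rw", "rw_dual", "ph", "aph")


@dataclass(frozen=True)
class ComparisonTable:
    """Pairwise mean AIC/BIC differences and per-subject winner counts.

    ``d_aic.loc[row, col]`` is the mean over subjects of
    ``AIC(row model) - AIC(col model)``; negative values favour the row
    model.  The matrices are antisymmetric by construction.
    """

    models: Tuple[str, ...]
    d_aic: pd.DataFrame
    d_bic: pd.DataFrame
    aic_winners: Dict[str, int]
    bic_winners: Dict[str, int]
    n_subjects: int

    def to_csv(self, path) -> None:
        """Lower-triangular long-format CSV of the pairwise mean deltas."""
        rows = []
        for i, m_row in enumerate(self.models):
            for m_col in self.models[:i]:
                rows.append({
                    "model": m_row, "versus": m_col,
                    "d_aic": self.d_aic.loc[m_row, m_col],
                    "d_bic": self.d_bic.loc[m_row, m_col],
                    "aic_wins_model": self.aic_winners[m_row],
                    "bic_wins_model": self.bic_winners[m_row],
                })
        pd.DataFrame(rows).to_csv(path, index=False)


def compare_models(fits: Mapping[int, Mapping[str, FitResult]]
                   ) -> ComparisonTable:
    """Table-style model comparison across a cohort of fitted subjects."""
    subjects = sorted(fits)
    if not subjects:
        raise ValueError("no fits supplied")
    model_set = set(fits[subjects[0]])
    for s in subjects:
        if set(fits[s]) != model_set:
            raise ValueError(f"subject {s} is missing fits for some models")
    models = tuple(m for m in _MODEL_ORDER if m in model_set)

    aic = pd.DataFrame({m: [fits[s][m].aic for s in subjects] for m in models},
                       index=subjects)
    bic = pd.DataFrame({m: [fits[s][m].bic for s in subjects] for m in models},
                       index=subjects)

    def pairwise(values: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(0.0, index=list(models), columns=list(models))
        for mr in models:
            for mc in models:
                out.loc[mr, mc] = float((values[mr] - values[mc]).mean())
        return out

    def winners(values: pd.DataFrame) -> Dict[str, int]:
        w = values.idxmin(axis=1).value_counts()
        return {m: int(w.get(m, 0)) for m in models}

    return ComparisonTable(models=models, d_aic=pairwise(aic),
                           d_bic=pairwise(bic), aic_winners=winners(aic),
                           bic_winners=winners(bic), n_subjects=len(subjects))


@dataclass(frozen=True)
class LRTResult:
    """Fixed-effects likelihood-ratio test of a nested model pair."""

    chi_square: float
    df: int
    p_value: float
    per_subject: pd.Series


def fixed_effects_lrt(fits_restricted: Mapping[int, FitResult],
                      fits_full: Mapping[int, FitResult],
                      df_per_subject: Optional[int] = None) -> LRTResult:
    """Sum per-subject likelihood-ratio improvements of a nested pair.

    chi^2 = sum over subjects of max(0, 2 * (loglik_full - loglik_restricted))
    (clipped at zero to guard against optimiser noise in the nested fit),
    with df = n_subjects * df_per_subject.  ``df_per_subject`` defaults to
    the difference in free-parameter counts.
    """
    subjects = sorted(fits_restricted)
    if sorted(fits_full) != subjects:
        raise ValueError("restricted and full fits cover different subjects")
    if not subjects:
        raise ValueError("no fits supplied")
    r0 = fits_restricted[subjects[0]]
    f0 = fits_full[subjects[0]]
    if (r0.model, f0.model) not in NESTED_PAIRS:
        raise ValueError(
            f"{r0.model!r} is not registered as nested in {f0.model!r}")
    if df_per_subject is None:
        df_per_subject = f0.n_free - r0.n_free
    if df_per_subject < 1:
        raise ValueError("df_per_subject must be >= 1")
    per = pd.Series({
        s: max(0.0, 2.0 * (fits_full[s].loglik - fits_restricted[s].loglik))
        for s in subjects
    })
    chi = float(per.sum())
    df = len(subjects) * df_per_subject
    return LRTResult(chi_square=chi, df=df,
                     p_value=float(stats.chi2.sf(chi, df)), per_subject=per)


# ---------------------------------------------------------------------------
# Per-SD learning-rate refits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupRatesFit:
    """Non-adaptive PH refit with a separate initial learning rate per group.

    ``rates`` maps the grouping key (condition SD by default) to the fitted
    initial gain alpha; gamma and C are shared across groups, and
    sigma_hat_sq is profiled as in :func:`fit_subject`.
    """

    rates: Dict[object, float]
    gamma: float
    C: float
    sigma_hat_sq: float
    loglik: float
    n_obs: int
    n_free: int
    converged: bool


def fit_group_learning_rates(trials: pd.DataFrame, by: str = "sd",
                             restarts: int = 10,
                             rng: Optional[np.random.Generator] = None,
                             y0: float = SCALE_MIDPOINT,
                             tol: float = 1e-6) -> GroupRatesFit:
    """Per-group initial learning rates for one subject (PH refit).

    ``by`` is a trial-table column ("sd" pools the two EV conditions of each
    SD; "condition_id" estimates one rate per condition, as needed for the
    context analysis of the two SD-10 conditions).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    conds = _prepare(trials, group_col=by)
    groups = sorted({c.group for c in conds})
    n_g = len(groups)
    index = {g: i for i, g in enumerate(groups)}

    def objective(x: np.ndarray) -> float:
        alphas = x[:n_g]
        resid = _resid_ph(lambda g: alphas[index[g]], x[n_g], x[n_g + 1],
                          0.0, DEFAULT_D, conds, y0)
        return _profiled_nll(resid)[0]

    bounds = [PARAM_BOUNDS["alpha"]] * n_g + [PARAM_BOUNDS["gamma"],
                                              PARAM_BOUNDS["C"]]
    best_fun, best_x, best_ok = math.inf, None, False
    for _ in range(restarts):
        x0 = np.concatenate([
            rng.uniform(0.0, 1.0, size=n_g),
            [rng.uniform(0.0, 1.0), rng.uniform(1e-6, 0.2)],
        ])
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": tol, "maxiter": 500})
        if res.fun < best_fun:
            best_fun, best_x, best_ok = float(res.fun), res.x, bool(res.success)
    assert best_x is not None
    alphas = best_x[:n_g]
    resid = _resid_ph(lambda g: alphas[index[g]], best_x[n_g], best_x[n_g + 1],
                      0.0, DEFAULT_D, conds, y0)
    nll, sigma_sq = _profiled_nll(resid)
    return GroupRatesFit(
        rates={g: float(alphas[index[g]]) for g in groups},
        gamma=float(best_x[n_g]), C=float(best_x[n_g + 1]),
        sigma_hat_sq=sigma_sq, loglik=-nll, n_obs=len(resid),
        n_free=n_g + 3, converged=best_ok,
    )


def mean_early_gain(trials: pd.DataFrame, fit: GroupRatesFit, by: str = "sd",
                    n_early: int = 7, y0: float = SCALE_MIDPOINT
                    ) -> Dict[object, float]:
    """Mean PH gain over the first ``n_early`` trials, per group.

    Companion summary to the per-group initial rates: replays the fitted PH
    gain recursion over the observed prediction errors and averages the gain
    across each group's early trials.
    """
    conds = _prepare(trials, group_col=by)
    sums: Dict[object, float] = {}
    counts: Dict[object, int] = {}
    for c in conds:
        k = fit.rates[c.group]
        mu = y0
        for i, (y, r, m) in enumerate(zip(c.y, c.r, c.missed)):
            if i < n_early:
                sums[c.group] = sums.get(c.group, 0.0) + k
                counts[c.group] = counts.get(c.group, 0) + 1
            yu = mu if m else y
            d = r - yu
            mu = yu + k * d
            k = min(1.0, max(0.0, fit.gamma * fit.C * abs(d)
                             + (1.0 - fit.gamma) * k))
    return {g: sums[g] / counts[g] for g in sums}
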