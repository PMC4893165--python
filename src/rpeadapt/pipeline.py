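"""End-to-end pipeline: simulate -> fit -> compare -> adapt -> neural -> report.

Library orchestration of the full analysis on a synthetic cohort.  A
:class:`PipelineConfig` (round-trippable through YAML/JSON) drives every
stage; a master seed propagates deterministic sub-seeds to each stage, so
re-running the same configuration reproduces every artifact byte for byte.
Artifacts are plain CSV/JSON plus a Markdown report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import adaptation, fitting, neural, task
from .models import ModelParams
from .task import TaskConfig, TRIAL_COLUMNS

logger = logging.getLogger("rpeadapt.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


class TrialTableError(ValueError):
    """A trial table violates its schema; all violations are listed."""

    def __init__(self, violations: Sequence[str]):
        super().__init__(
            "invalid trial table:\n  - " + "\n  - ".join(violations))
        self.violations = list(violations)


@dataclass(frozen=True)
class NeuralSettings:
    """Neural-simulation settings shared across the cohort.

    Per-subject adaptive-coding strength psi is coupled to the behavioral
    adaptation weight nu with Gaussian jitter ``psi_jitter``.
    """

    base_slope: float = 1.0
    noise_sd: float = 3.0
    sign_asymmetry: float = 1.0
    phase_ramp: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    psi_jitter: float = 0.15


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_subjects: int = 27
    generative_model: str = "aph"
    nu_range: Tuple[float, float] = (0.0, 1.0)
    models: Tuple[str, ...] = ("bayes", "rw", "ph", "aph")
    restarts: int = 10
    neural: NeuralSettings = field(default_factory=NeuralSettings)
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise task.ConfigError("n_subjects must be >= 1")
        if len(set(self.task.sds)) < 3:
            raise task.ConfigError(
                "the adaptation analyses need at least 3 distinct SD levels")
        from .models import MODEL_IDS
        for m in (self.generative_model, *self.models):
            if m not in MODEL_IDS:
                raise task.ConfigError(f"unknown model {m!r}")
        if self.restarts < 1:
            raise task.ConfigError("restarts must be >= 1")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        d = dict(d)
        t = dict(d.pop("task", {}))
        if "session_sd_pairs" in t:
            t["session_sd_pairs"] = tuple(tuple(p) for p in t["session_sd_pairs"])
        for key in ("sds", "evs", "block_range"):
            if key in t:
                t[key] = tuple(t[key])
        n = dict(d.pop("neural", {}))
        if "phase_ramp" in n:
            n["phase_ramp"] = tuple(n["phase_ramp"])
        for key in ("models", "nu_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(task=TaskConfig(**t), neural=NeuralSettings(**n), **d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_trial_table(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    """Validate a trial table against the documented schema.

    Checks column presence, bounds (predictions and rewards on the 0-100
    scale), internal consistency (rpe = reward - prediction on non-missed
    trials) and flag types; every violation is collected and reported at
    once, not first-failure.  Returns the typed table with the observed
    control fraction attached as ``df.attrs['control_fraction']``.
    """
    df = task.read_trials(source) if not isinstance(source, pd.DataFrame) \
        else source.copy()
    violations: List[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError([f"missing columns: {missing}"])
    df["is_control"] = df["is_control"].astype(bool)
    df["missed"] = df["missed"].astype(bool)
    live = ~df["missed"]

    bad = df.loc[live & ~df["prediction"].between(0, 100)]
    if not bad.empty:
        violations.append(
            f"{len(bad)} predictions outside [0, 100] "
            f"(first at row {bad.index[0]}: {bad['prediction'].iloc[0]!r})")
    bad = df.loc[~df["reward"].between(0, 100)]
    if not bad.empty:
        violations.append(f"{len(bad)} rewards outside [0, 100]")
    rpe_err = (df.loc[live, "rpe"]
               - (df.loc[live, "reward"] - df.loc[live, "prediction"])).abs()
    bad_idx = rpe_err[rpe_err > 1e-6]
    if not bad_idx.empty:
        violations.append(
            f"{len(bad_idx)} trials where rpe != reward - prediction "
            f"(first at row {bad_idx.index[0]})")
    if (df["sd"] <= 0).any():
        violations.append("non-positive SD values present")
    if (df["trial_in_condition"] < 1).any():
        violations.append("trial_in_condition must be 1-based")
    if df.loc[live & ~df["is_control"], "payoff"].sub(
            df.loc[live & ~df["is_control"], "reward"] / 10.0).abs().gt(1e-6).any():
        violations.append("main-trial payoff must equal reward / 10")

    if violations:
        raise TrialTableError(violations)
    df.attrs["control_fraction"] = float(df["is_control"].mean())
    return df


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        logger.error("stage %s: failed (%s)", name, exc)
        raise PipelineStageError(name, exc) from exc
    logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run the full synthetic-cohort analysis; returns artifact paths.

    Stages: simulate a cohort under the configured generative model; fit all
    candidate models per subject; compare them (pairwise mean dAIC/dBIC and
    winner counts); likelihood-ratio test of adaptive vs plain PH; per-SD
    learning-rate refits, behavioral adaptation Omega and performance error;
    simulated neural responses, coding slopes, neural adaptation Psi and the
    normalised-vs-raw comparison; and a JSON + Markdown report with the
    recovery diagnostics.  Any stage failure raises
    :class:`PipelineStageError` with earlier artifacts preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    master = np.random.default_rng(config.seed)
    sim_rng, fit_rng, rates_rng, psi_rng, neural_rng = master.spawn(5)
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)  # report content independent of where it lives
    report: Dict[str, object] = {"config": cfg_dict}

    with _stage("simulate"):
        sampler = task.cohort_param_sampler(config.generative_model,
                                            nu_range=config.nu_range)
        trials, truth = task.simulate_cohort(
            config.n_subjects, config.generative_model, sampler,
            config.task, sim_rng)
        paths["trials"] = out / "trials.csv"
        task.write_trials(trials, paths["trials"])
        paths["truth"] = out / "truth.json"
        task.write_truth(truth, paths["truth"])
        validate_trial_table(paths["trials"])

    with _stage("fit"):
        fits = fitting.fit_cohort(trials, models=config.models,
                                  restarts=config.restarts, rng=fit_rng)
        paths["fits"] = out / "fits.json"
        _json_dump({str(s): {m: f.to_dict() for m, f in by_model.items()}
                    for s, by_model in fits.items()}, paths["fits"])

    with _stage("compare"):
        table = fitting.compare_models(fits)
        paths["comparison"] = out / "comparison.csv"
        table.to_csv(paths["comparison"])
        report["aic_winners"] = table.aic_winners
        report["bic_winners"] = table.bic_winners
        if "ph" in config.models and "aph" in config.models:
            lrt = fitting.fixed_effects_lrt(
                {s: f["ph"] for s, f in fits.items()},
                {s: f["aph"] for s, f in fits.items()})
            report["lrt_ph_vs_aph"] = {
                "chi_square": lrt.chi_square, "df": lrt.df,
                "p_value": lrt.p_value}

    with _stage("adapt"):
        rows = []
        omegas: Dict[int, float] = {}
        for subject in sorted(trials["subject"].unique()):
            sub = trials[trials["subject"] == subject]
            rates = fitting.fit_group_learning_rates(
                sub, by="sd", restarts=config.restarts,
                rng=rates_rng.spawn(1)[0])
            res = adaptation.behavioral_adaptation(rates.rates)
            omegas[int(subject)] = res.r_squared
            row = {"subject": int(subject),
                   **{f"alpha_sd{sd:g}": a for sd, a in rates.rates.items()},
                   "gamma": rates.gamma, "C": rates.C,
                   "omega_beta0": res.beta0, "omega_beta1": res.beta1,
                   "omega": res.r_squared}
            if config.generative_model == "aph":
                row["true_nu"] = truth[int(subject)].nu
            rows.append(row)
        adapt_df = pd.DataFrame(rows)
        paths["adaptation"] = out / "adaptation.csv"
        adapt_df.to_csv(paths["adaptation"], index=False)

        perf = adaptation.performance_error(trials)
        paths["performance"] = out / "performance.csv"
        perf.per_condition.to_csv(paths["performance"], index=False)
        report["mean_performance_error"] = float(perf.per_subject.mean())

    with _stage("neural"):
        if config.generative_model == "aph":
            nu_by_subject = {s: p.nu for s, p in truth.items()}
        else:
            nu_by_subject = {s: float(psi_rng.uniform())
                             for s in sorted(truth)}
        psi = neural.psi_from_nu(nu_by_subject, psi_rng,
                                 jitter=config.neural.psi_jitter)
        responses = neural.simulate_cohort_responses(
            trials, psi, neural_rng,
            base_slope=config.neural.base_slope,
            noise_sd=config.neural.noise_sd,
            sign_asymmetry=config.neural.sign_asymmetry,
            phase_ramp=config.neural.phase_ramp)
        paths["responses"] = out / "neural_responses.csv"
        responses.to_csv(paths["responses"], index=False)

        slopes = neural.estimate_slopes(responses, by=("subject", "sd"))
        paths["slopes"] = out / "neural_slopes.csv"
        slopes.to_csv(paths["slopes"], index=False)

        psis = neural.adaptation_by_subject(responses)
        nvr = neural.normalized_vs_raw(responses)
        neural_df = pd.DataFrame({
            "subject": psis.index, "psi": psis.to_numpy(),
            "psi_true": [psi[int(s)] for s in psis.index],
            "coef_raw": nvr.per_subject["coef_raw"].reindex(psis.index).to_numpy(),
            "coef_norm": nvr.per_subject["coef_norm"].reindex(psis.index).to_numpy(),
        })
        paths["neural_adaptation"] = out / "neural_adaptation.csv"
        neural_df.to_csv(paths["neural_adaptation"], index=False)

    with _stage("report"):
        omega_s = pd.Series(omegas).sort_index()
        psi_s = psis.sort_index()
        perf_s = perf.per_subject.sort_index()
        if config.n_subjects >= 4:
            rho_op, p_op = adaptation.rank_correlation(omega_s, psi_s)
            rho_pp, p_pp = adaptation.rank_correlation(psi_s, perf_s)
            report["spearman_omega_psi"] = {"rho": rho_op, "p": p_op}
            report["spearman_psi_performance"] = {"rho": rho_pp, "p": p_pp}
        report["mean_omega"] = float(omega_s.mean())
        report["mean_psi"] = float(psi_s.mean())
        paths["report_json"] = out / "report.json"
        _json_dump(report, paths["report_json"])
        paths["report_md"] = out / "report.md"
        paths["report_md"].write_text(_render_report(report))

    return paths


def _render_report(report: Mapping[str, object]) -> str:
    lines = ["# Synthetic-cohort analysis report", ""]
    cfg = report["config"]
    lines.append(f"- subjects: {cfg['n_subjects']}, generative model: "
                 f"`{cfg['generative_model']}`, seed: {cfg['seed']}")
    lines.append(f"- fitted models: {', '.join(cfg['models'])} "
                 f"({cfg['restarts']} restarts)")
    lines.append("")
    lines.append("## Model comparison (per-subject AIC/BIC winners)")
    lines.append("")
    lines.append("| model | AIC wins | BIC wins |")
    lines.append("|---|---|---|")
    for m in cfg["models"]:
        lines.append(f"| {m} | {report['aic_winners'].get(m, 0)} "
                     f"| {report['bic_winners'].get(m, 0)} |")
    if "lrt_ph_vs_aph" in report:
        lrt = report["lrt_ph_vs_aph"]
        lines += ["", "## Fixed-effects likelihood-ratio test (PH vs adaptive PH)",
                  "",
                  f"chi2({lrt['df']}) = {lrt['chi_square']:.2f}, "
                  f"p = {lrt['p_value']:.3g}"]
    lines += ["", "## Adaptation and performance", "",
              f"- mean behavioral adaptation Omega: {report['mean_omega']:.3f}",
              f"- mean neural adaptation Psi: {report['mean_psi']:.3f}",
              f"- mean performance error: "
              f"{report['mean_performance_error']:.2f} pounds"]
    if "spearman_omega_psi" in report:
        so = report["spearman_omega_psi"]
        sp = report["spearman_psi_performance"]
        lines += [f"- Spearman rho(Omega, Psi) = {so['rho']:.3f} "
                  f"(p = {so['p']:.3g})",
                  f"- Spearman rho(Psi, performance error) = {sp['rho']:.3f} "
                  f"(p = {sp['p']:.3g})"]
    lines.append("")
    return "\n".join(lines)
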