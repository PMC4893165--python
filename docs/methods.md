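# Methods

This note documents the models, the synthetic-data generators, and the
numerical choices behind `rpeadapt`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

Rewards are integer pound amounts on a bounded scale [0, 100], drawn from
"pseudo-Gaussian" distributions with EV ∈ {35, 65} and SD ∈ {5, 10, 15}.
The generator realises this as: sample Normal(μ′, σ′), round to the nearest
integer, reject and redraw outside the scale.  Rounding and truncation
perturb both moments (at EV 35, SD 15 truncation alone shifts the mean by
≈ +0.4 and shrinks the SD by ≈ 4%), so (μ′, σ′) are calibrated once per
condition by a two-dimensional root solve on the exact moments of the
discrete post-rounding/truncation distribution (a 101-point pmf).  The
calibrated population mean and SD match the nominal values to < 10⁻⁶;
sampling noise in a 10,000-draw check is then the only source of deviation
(SE ≈ SD/√(2n) ≈ 0.11 for SD 15).  A degenerate SD = 0 distribution is
supported for tests.

**Schedule.**  Three sessions, each alternating two SD conditions in blocks
of 4–6 trials (uniformly random compositions of the per-condition trial
count, interleaved so consecutive blocks never repeat a condition).  The SD
pairings are {5,10}, {10,15}, {5,15} — SD 10 thus occurs once with a lower
and once with a higher partner, which is what the context analysis needs —
with session order and the assignment of the two EVs to each SD's two
occurrences randomised per subject.

**Trials per condition: 25.**  Two constraints interact: the control-trial
fraction must be exactly 20%, and the phase analysis needs the 21-trial
early/middle/late window (7/7/7).  No multiple of 21 makes 20% an integer
count, so the canonical schedule uses 25 trials per condition (5 of them
control trials); trials 22–25 fall outside the phase window and are tagged
`post`.  Recovery simulations use a 21-trial, no-control configuration (126
trials per agent): control trials are ordinary learning trials — only their
payoff rule differs (main trials pay reward/10; control trials pay a
performance-based, SD-scaled amount, configurable) — so the distinction is
irrelevant to fitting.  Missed trials are generated only when a positive
miss probability is configured (default 0).

**Agents.**  A simulated agent's internal prediction follows its model's
recursion; the *emitted* prediction adds Gaussian noise with variance σ̂²
(simulation preset: 25, i.e. ±5 pounds on the 0–100 scale) and is clipped to
the scale, and the recursion then conditions on the emitted value.  This
makes the generative process identical to the one-step-ahead likelihood used
in fitting, so recovery tests probe the estimator rather than a model
mismatch.  The internal starting prediction is the scale midpoint (50); the
initial on-screen bar position in the real task is irrelevant to the models.
Cohort samplers draw per-subject true parameters α ~ U(0.1, 0.9),
γ ~ U(0.2, 0.8), ν ~ U(0, 1) (narrowed to U(0.6, 1) for "strongly adaptive"
cohorts used in model-comparison checks), with C fixed at 0.05 gain per
pound of |RPE|.

## Learning models

All models share y[n+1] = y[n] + k[n]·δ[n] with per-condition state reset
(each condition has its own cue and reward stream; parameters are shared
across conditions within a subject).

- **Bayesian mean tracker**: k is the Kalman gain σ²ₙ₋₁/(σ²ₙ₋₁ + σ²); the
  posterior variance σ²ₙ = σ²ₙ₋₁σ²/(σ²ₙ₋₁ + σ²) strictly decreases, matching
  the conjugate-Gaussian closed form σ²σ₀²/(σ² + nσ₀²).  Because the assumed
  reward variance is SD-specific, the model carries one free σ² per SD
  condition; the prior mean is fixed at the scale midpoint.
- **Rescorla–Wagner**: constant k = α; the dual-rate variant routes positive
  δ through α⁺ and negative δ through α⁻ (δ = 0 uses α⁺ — a measure-zero
  event under continuous rewards, fixed for determinism).
- **Pearce–Hall**: kₙ₊₁ = γ·C·|δₙ| + (1−γ)·kₙ, initialised at k₀ = α.  The
  raw recursion can exceed 1 for large |δ| (C·|δ| up to 20 at the bounds),
  which on a bounded scale produces oscillatory divergence; the gain is
  therefore clipped to [0, 1] — the minimal stabilisation.
- **Adaptive Pearce–Hall**: the PH update with δ divisively scaled by
  ω = (1−ν) + ν·log(SD)/D in both the prediction and the gain recursions.
  D is fixed at log(5) so ω = 1 at the smallest SD and ω > 1 (compression)
  for larger SDs; ν ∈ [0, 1] is the per-subject adaptation weight.  ν = 0
  reproduces plain PH exactly; γ = 0 reproduces RW exactly — both
  equivalences are tested to machine precision.

## Fitting

Maximum likelihood per subject: p(yₘ | Φ) = N(μₘ, σ̂²) where μₘ is the
model's one-step-ahead prediction conditioned on the subject's *observed*
previous predictions and rewards (the standard identifiable choice for
recursive rules; conditioning on self-generated trajectories propagates
early errors and is not used).  The first trial of each condition is
evaluated against the initial prediction y₀ = 50, which is exactly the
emitting agents' starting point (and the Bayesian prior mean), so no trial
is discarded.  Missed trials are excluded from the likelihood; the state
advances on the reward alone, substituting the model's own prediction.  The
Gaussian density is evaluated on the unclipped μₘ.

Optimisation is bounded multi-start L-BFGS-B (default 10 uniform-in-bounds
restarts; log-uniform for variance-like parameters; NLL tolerance 10⁻⁶).
σ̂² is profiled out analytically at every objective evaluation — its
conditional MLE is the mean squared residual, clamped to (10⁻³, 10³) — which
removes one search dimension without changing the maximum; σ̂² still counts
as a free parameter in AIC/BIC.  Bounds: α, γ, ν, α± ∈ [0, 1];
C ∈ (10⁻⁶, 0.2] (C is not identifiable jointly with γ at the extremes);
σ², σ₀² ∈ (10⁻³, 10⁴).  When several models are fitted to one subject, each
nested pair is warm-started from its restriction's solution (RW → PH with
γ = 0; PH → adaptive PH with ν = 0; RW → dual-rate), which guarantees the
nested log-likelihood ordering up to optimiser tolerance and stabilises the
likelihood-ratio test, whose per-subject statistic is additionally clipped
at zero against optimiser noise.  Refits with identical seeds are
bit-identical, and more restarts can only improve (weakly) the best NLL.

Model comparison reports pairwise mean ΔAIC/ΔBIC across subjects (negative
favouring the row model) plus per-subject winner counts.  The fixed-effects
likelihood-ratio test sums per-subject 2·Δlog-likelihood with
df = subjects × df-per-subject; df-per-subject defaults to the
free-parameter difference but is an explicit argument, because published df
bookkeeping for such tests varies.

**Per-SD learning rates** (for the adaptation index) come from refitting the
non-adaptive PH model with a separate initial rate α per SD condition
(pooling the two EVs) and shared γ, C.  The same machinery with one α per
*condition* serves the SD-10 context analysis.  Since "initial learning
rate" could also mean the average early-trial gain, `mean_early_gain`
replays the fitted gain recursion and averages k over each condition's first
seven trials; the per-SD α is the default index input.

## Adaptation indices and performance

Ω and Ψ are the R² of a two-parameter OLS of three per-SD values (learning
rates or coding slopes) on SD⁻¹.  A constant response defines R² = 0 (and is
flagged); floating-point R² is clamped to [0, 1].  A companion comparison
fits the same values with a zero-centred linear contrast (1, 0, −1) to ask
whether the decrease over SD is non-linear (inverse-SD-shaped) or linear.
Task performance is mean |prediction − EV| over non-missed trials — it
penalises both instability and bias.  Rank correlations are tie-aware
Spearman ρ; constant vectors raise instead of returning an undefined value.
Cohort-level plots/tests can use per-subject z-scoring (`zscore_per_subject`);
regressions always use raw values.

A caveat worth stating: a three-point R² has a single error degree of
freedom.  Its null distribution is broad (mean ≈ 0.5), it saturates near 1
whenever the true values are monotone in SD⁻¹ and noise is small, and a
single estimate is intrinsically noisy.  The test suite therefore evaluates
Ψ-recovery as monotonicity of the mean index over a ψ grid and as rank
correlation of the index *averaged over repeated response simulations*, and
interprets single-cohort correlations as direction checks only.

## Synthetic neural responses

Per-trial scalar amplitudes stand in for event-related responses:
response = b·[(1−ψ) + ψ·SDref/SD]·δ·s(δ) + ε, SDref = 5, ε ~ N(0, noise).
The gain is *exactly* linear in SD⁻¹, so ψ interpolates between absolute
coding (ψ = 0, equal slopes) and fully normalised coding (ψ = 1, slope ∝
1/SD); s(δ) optionally amplifies responses to negative RPEs, and a per-phase
multiplier on ψ lets adaptation ramp across early/middle/late trials.  This
deliberately omits all imaging machinery (HRF convolution, design matrices,
multiple-comparison corrections, anatomy): those add no testable content at
desk scale, while the slope-level quantities — per-SD coding slopes, Ψ, the
normalised-vs-raw comparison, phase effects, sign effects — are preserved
exactly.  Response units are arbitrary; only ratios and orderings carry
meaning.  The default noise scale (3 response units, giving per-condition
slope standard errors around 8–10% of the reference slope) was chosen so the
R²-based index operates in its informative range rather than saturating.

Slopes are estimated per group (SD × phase × sign as requested) by least
squares of the response on δ with reward magnitude partialled out, so the
slope reflects prediction-error coding independent of outcome value; groups
with constant δ or fewer than 3 trials raise.  The normalised-vs-raw
comparison z-scores δ and δ/SD per subject across all conditions and enters
them *jointly* (with z-scored reward value, no serial orthogonalisation), so
each coefficient reflects uniquely explained variance; with a single SD the
two regressors are collinear and the function raises a dedicated error.
Where behavioral and neural adaptation are coupled, ψ = clip(ν + N(0, 0.15))
links a subject's neural gain adaptation to their behavioral scaling weight.

## Pipeline and reproducibility

`run_pipeline` chains simulate → fit → compare → adaptation → neural →
report from a single `PipelineConfig` (losslessly YAML/JSON-serialisable).
A master seed spawns independent child generators per stage and per subject
in a fixed order, so identical configurations reproduce every artifact byte
for byte (reports contain no timestamps or absolute paths).  Stage failures
raise a stage-tagged error with earlier artifacts preserved.  Trial tables
are validated exhaustively (bounds, RPE consistency, payoff rule, flags),
reporting all violations at once.

## Problem sizes used by the test suite

Recovery and model-comparison checks use 27-agent cohorts with 126 trials
per agent and 10 restarts (RW α recovery, ν rank recovery, AIC confusion
matrix).  The likelihood-ratio direction check uses 5 seeds × 12 agents × 5
restarts; the context-effect check pools 3 seeds × 27 agents of
per-condition refits; neural direction checks use 27-subject cohorts with
10 repeated response simulations where an index is averaged.  The full suite
runs in a few minutes on one CPU.

## Known limitations

- The synthetic cohorts emulate the task's statistical structure, not human
  behaviour: no reaction times, lapses beyond a miss flag, drift in
  strategy, or working-memory covariates.  Passing recovery tests shows the
  estimator works under the generative assumptions, not that the models are
  true of people.
- The Bayesian tracker is fitted in the same one-step-ahead scheme as the
  other models; its σ² parameters then absorb gain dynamics and need not
  match the true reward variances.
- Gain clipping makes the PH likelihood surface piecewise smooth; with
  bounded C this matters only at extreme |δ|.
- Published group statistics from the original human cohort (F/T/χ²/ρ
  values, AIC/BIC tables) are cohort-specific and are not reproduction
  targets; the package reproduces design constants and effect directions.
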