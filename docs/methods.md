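# Methods

This note documents the models, the estimation machinery, the synthetic
data conditions, and the numerical and design choices behind them.

## Task model

Two variants of the two-step task are generated:

* **magnitude** — 300 trials; each of the four second-stage options pays a
  continuous magnitude drifting in [0, 100], rounded to the nearest
  integer;
* **probability** — 200 trials; each option pays 1 with a probability
  drifting in [0.25, 0.75].

First-stage actions map to second-stage states through a fixed transition
structure: each action has one *common* destination reached with
probability `p_common = 0.7`, the other state otherwise. The mapping
(which state is common for action 0) is a config field; the default sends
action 0 to state B.

Outcome drifts are independent reflecting Gaussian random walks. The drift
step SD is not uniquely determined by the task descriptions, so we use
conventional values exposed as config: 2.5 (2.5 % of range) for the
magnitude variant and 0.025 for the probability variant. Initial values
are uniform within the bounds. Reflection is implemented by folding the
*free* cumulative walk at the boundaries; this is distributionally
identical to reflecting each increment (for symmetric steps) and is exactly
what the test oracle checks. Magnitude walks are rounded at emission.

## Model variants

Six variants cross perseveration scheme (first- vs. higher-order) with a
directed-exploration bonus (none / bandit counter / trial counter):
`q_fop`, `q_bandit`, `q_trial`, `q_hop`, `q_bandit_hop`, `q_trial_hop`.

Shared learner (rewards rescaled to [0, 1]; see *Numerical choices*):

1. SARSA update of the chosen first-stage value with the stage-1
   prediction error `δ₁ = Q₂(s₂, a₂) − Q_MF(s₁, a₁)` at rate `α₁`
   (pre-update `Q₂`);
2. stage-2 update `Q₂ += α₂ (r − Q₂)` and transfer of the same stage-2
   prediction error to the first stage at rate `α₂` (in place of an
   eligibility-trace parameter);
3. forgetting: the unchosen first-stage value and the unchosen option of
   the *visited* second-stage state decay toward the mid-range,
   `Q ← α₃ Q + (1 − α₃)·0.5`. Whether the unvisited state's options also
   decay is ambiguous in this model family; we default to the literal
   visited-state-only reading and expose `decay_all` as a switch;
4. HOP variants: habit trace `H(a) ← H(a) + α_HOP (rep(a) − H(a))` for
   both actions, with `rep` the chosen-action indicator. At `α_HOP = 1`
   the trace equals the indicator and HOP reduces exactly to FOP (a
   machine-precision identity covered by tests);
5. sampling counters (used by the exploration bonuses) track the global
   option index `n = 2·state + action`: choosing `n` clears its
   distinct-alternatives set and resets its trial counter to 1; every
   other option's set gains `n` (bandit counter = set size, at most 3) and
   its trial counter increments.

Choice rules: stage 1 is a SoftMax over
`β_MB·Q_MB + β_MF·Q_MF + β_persev·pers + φ·eb` where `pers` is `rep(a)`
(FOP) or `H(a)` (HOP) and `eb` is the transition-weighted per-state sum of
the bandit counters or of `max(0, ln t)` trial counters; stage 2 is a
SoftMax over `β₂·Q₂`. At `φ = 0` the exploration variants reduce exactly
to their base models.

The bandit bonus lies in [0, 6]; the trial bonus in [0, 2·ln T].

### A note on value bounds

With unit-scale rewards, `Q₂` stays in [0, 1] (all its updates are convex
combinations of values in [0, 1]), as does the habit trace. The
first-stage MF value does **not** share this guarantee: the stage-2
prediction-error transfer (`Q_MF += α₂ δ₂`) is not convex in `Q_MF`, and
with a small `α₁` persistent same-signed stage-2 errors can push
`Q_MF(s₁)` outside [0, 1]. The equations are implemented as printed; tests
assert boundedness only where it actually holds.

## Likelihood

A subject's sequence log-likelihood is
`Σ_t [ln P(a₁,t | history) + ln P(a₂,t | history)]` over valid trials; the
per-trial sum of both stages is the pointwise unit used by LOO and WAIC
(configurable in principle; trial-level is the package's convention and
gives well-behaved SEs).

Invalid trials (e.g. responses faster than the 150 ms filter) contribute
nothing to the likelihood, and their value/habit updates and the
perseveration reference are skipped; the sampling counters still advance,
because the subject did observe the outcome. Stay analyses likewise bridge
excluded trials: stay is defined against the previous *valid* trial.

Two implementations exist and are held equal by tests: a readable
pure-Python recursion (`twostep.latent`) and allocation-free numba kernels
(`twostep._core`) used by sampling and simulation.

## Hierarchical estimation

Subject-level raw parameters `θ_s,k` are modelled as draws from group-level
Gaussians with mean `M^k ~ Normal(0, 10)` and SD `Λ^k ~ Uniform(0, 10)`
(rates) or `Uniform(0, 20)` (SoftMax weights, exploration weight). Rates
enter the likelihood through the standard-normal CDF; other parameters are
unbounded (no hard ±10 clamp on raw values — the CDF transform makes one
redundant). The CDF output is clipped to `[1e-12, 1 − 1e-12]` because the
double-precision CDF saturates to exactly 0/1 beyond |raw| ≈ 8.3.

### Sampler

The posterior is sampled by a native Metropolis-within-Gibbs scheme on the
centered parameterization:

* **subject level** — per-iteration: `n_scans` (default 5) single-site
  adaptive random-walk Metropolis scans over all `(subject, parameter)`
  sites; one scan of single-site *independence* proposals from the current
  group prior `N(M^k, Λ^k)` (prior and proposal cancel, so weakly
  identified parameters decorrelate in one step); and 4 full-vector
  Metropolis proposals per subject using per-subject proposal covariances
  adapted from warm-up draws (scaled 2.38²/K), which follow within-subject
  correlations such as the stage-2 learning-rate/inverse-temperature
  trade-off;
* **group level** — exact conjugate Gibbs draws for each `M^k` and
  stepping-out slice sampling for each `Λ^k`, plus interweaved
  *non-centered* moves that translate (`M^k`) or rescale (`Λ^k`) all
  subjects' raw values jointly: one random-walk and one independence
  (prior-draw) version of each, alternating across iterations. The
  non-centered moves break the funnel coupling that otherwise slows
  centered Gibbs for parameters the data barely constrain (typically
  `α₁`).

Proposal scales adapt toward 44 % (single-site) / 23 % (block) acceptance
in diminishing batches during warm-up and are frozen afterwards. Initial
values are drawn uniformly from [−2, 2] (group SDs from (0.1, 2]). The
reference settings are 4 chains × 10,000 iterations with 8,000 discarded
as warm-up (8,000 retained draws); the desk-scale default used by the test
suite (`SamplerConfig.test_scale()`) is 4 × 1,500 with 1,000 warm-up.
Convergence is monitored with classic split R-hat (verified against an
independent implementation); values ≤ 1.1 are considered acceptable, and a
fit that exceeds it is flagged, not failed.

We deliberately use the *centered* parameterization as the base scheme —
with 150–300 informative trials per subject it mixes well and gives
likelihood-free group updates — and recover non-centered behaviour through
the interweaved moves, rather than running a fully non-centered scheme
that would make every group-level update pay S likelihood evaluations.

Per retained draw, the per-trial pointwise log-likelihood of every subject
is recomputed by the kernel and stored; this feeds LOO, WAIC, and the
comparison table.

A deterministic alternative, `fit_map`, runs coordinate ascent: per-subject
penalized L-BFGS on the raw scale against the current group moments, then
closed-form group-mean (Normal prior) and group-SD updates, the latter
floored at 0.05 to avoid the usual hierarchical variance collapse of joint
modes. It is a fast point-estimate mode for checks, not the reference
path.

## Model comparison

PSIS-LOO (via arviz: generalized-Pareto smoothing of the top 20 % of
importance weights; Pareto-k > 0.7 flagged) gives each model's elpd and
SE. Differences to the best model use paired pointwise contributions,
`se_diff = sqrt(n · var(diff_i))`, and the evidence ratio
`|elpd_diff| / se_diff`. When a model's deficit overlaps zero within one
`se_diff`, the comparison table marks the most parsimonious such model
(fewest free parameters) as preferred. WAIC is computed directly as
`−2(lppd − p_waic)` with the sample-variance (S−1) penalty; note arviz
uses the population-variance convention, so the two differ by O(n/S).

## Model-agnostic analyses

Stays (repeating the previous first-stage choice) are coded against the
previous trial's reward and transition, both +1/−1 (rewarded/common = +1).
Magnitude-variant rewards are binarized against the mean of up to 20
immediately preceding valid rewards; the first trial uses the mid-range
(50) as reference, and exact ties code as unrewarded (strict "exceeds";
both choices are config-exposed). Difference scores follow the
two-by-two stay table:
`MF_diff = (P_c,r + P_r,r) − (P_c,u + P_r,u)`,
`MB_diff = (P_c,r + P_r,u) − (P_c,u + P_r,r)`.

The group stay regression (`stay ~ rew * trans`) is a Bayesian
hierarchical logistic model with subject-level random intercept and slopes,
sampled by the same Metropolis-within-Gibbs pattern (vectorized across
subjects) and reported as posterior means with 95 % HDIs — signs and
magnitudes, not p-values, are the inferential surface, which avoids a
second (frequentist mixed-model) estimation stack. Per-subject mode is
independent maximum-likelihood logistic regression; quasi-separated fits
are re-fit with a light ridge penalty, clipped to ±10 and flagged.

## Synthetic cohorts (the study conditions)

`default_cohort` draws subject-level raw parameters from group Gaussians
with means anchored to typical magnitude-variant group estimates under the
winning HOP model — rates `α₁ ≈ .38`, `α₂ ≈ .82`, `α₃ ≈ .99`,
`α_HOP ≈ .57` (via the inverse CDF), weights `β_MB = 10.59`,
`β_MF = 1.39`, `β_persev = 1.44`, `β₂ = 9.76`, `φ = 0.25` — and moderate
between-subject spreads (0.4 raw for rates; 3.5, 0.5, 0.5, 2.4, 0.15 for
the weights). Subject deviations are drawn from a ±2.5 SD symmetric
truncated Gaussian: untruncated tails occasionally produce a subject with
`β₂ ≈ 0`, whose second-stage choices are uninformative and whose
learning-rate/temperature posterior becomes a bimodal ridge that no
sampler traverses at desk scale — a pathology of the simulation, not of
the estimator, and standard practice in recovery studies is to keep every
simulated subject in an identifiable regime.

What the generator emulates: trial counts, transition structure, outcome
drift ranges, and plausible group-level parameter regimes for both task
variants. What it does not emulate: response times (none are generated;
the RT filter applies only to read-in data), practice/training effects,
within-session non-stationarity of parameters, missed responses, and any
stimulus-level effects. Passing recovery and signature tests therefore
shows the estimator and analysis chain are correct and well-calibrated
under the model's own assumptions — not that the model family is adequate
for any particular empirical dataset.

## Problem sizes used by the test suite

Chosen as the package's desk-scale conventions: parameter recovery uses 20
subjects × 300 trials at `test_scale` sampling (R-hat ≤ 1.1 and
true-vs-posterior-mean correlations > 0.5 for `β_MB` and `β_persev`);
model recovery uses five replicate 12-subject × 150-trial cohorts at 4
chains × 500 iterations; regression signatures use 10-subject × 250-trial
single-purpose cohorts; the PSIS-LOO oracle uses a 50-point conjugate
Gaussian problem where exact leave-one-out refits are closed-form.

## Numerical choices

* Magnitude rewards are divided by 100 before entering the learner so the
  forgetting target 0.5 is the mid-range of the value scale; probability
  rewards are used as 0/1.
* Initial values: all Q at 0.5 (the forgetting fixed point), habits at 0,
  bandit counters empty, trial counters at 1 (`ln 1 = 0`), no previous
  action (`rep ≡ 0` on trial 1).
* Update order within a trial is as listed above; `δ₁` uses pre-update
  `Q₂` (standard SARSA timing).
* SoftMax terms are evaluated with max-shifted log-sum-exp; choice
  probabilities are strictly inside (0, 1) for finite parameters.
* Degenerate inputs: `p_common = 1` is allowed (always-common
  transitions); zero walk-step SD gives constant outcome trajectories;
  zero group SDs give identical subjects.
* Seed discipline: every public entry point takes one seed and derives
  independent child streams (walks, transitions/choices, subject draws,
  chains) via `numpy.random.SeedSequence`; numba kernels are seeded per
  chain from the same tree. Identical inputs reproduce outputs bit-exactly.

## Known limitations

* The samplers are Metropolis-based; posteriors with strong ridge
  geometry (e.g. a subject whose `β₂` is effectively zero) mix slowly at
  desk-scale iteration counts. The truncated cohort generator avoids
  constructing such subjects; for empirical data the R-hat flag is the
  guard.
* `fit_map` point estimates shrink less adaptively than the full
  posterior and use an ad-hoc SD floor; use MCMC for inference.
* Eligibility-trace (λ) models, Kalman-filter learners, and
  drift-diffusion choice rules are out of scope.
* The exploration bonuses are heuristics; no attempt is made to model
  full Bayesian uncertainty tracking.
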