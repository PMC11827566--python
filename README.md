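# twostep

Hybrid model-based/model-free reinforcement-learning analysis of two-step
sequential decision task (TST) behaviour, with perseveration and
directed-exploration extensions, hierarchical Bayesian fitting, model
comparison and posterior predictive checks.

## The scientific problem

The two-step task is the workhorse paradigm for separating **model-based
(MB)** from **model-free (MF)** control of choice. On each trial a
first-stage choice leads — through a fixed 70/30 transition structure — to
one of two second-stage states, where a second choice pays either a
drifting reward magnitude in 0–100 (*magnitude* variant, 300 trials) or a
binary reward with drifting probability (*probability* variant, 200
trials). MF control repeats whatever was rewarded; MB control evaluates
actions through the transition model, producing the signature
reward-by-transition interaction in stay probabilities.

Standard hybrid models of this task capture only first-order perseveration
(a bonus for repeating the immediately preceding choice). This package
implements an extended model space of six variants crossing:

* **perseveration scheme** — first-order (FOP: indicator `rep(a)`) vs.
  higher-order (HOP: a value-free habit trace
  `H_t = H_{t-1} + α_HOP (rep(a) − H_{t-1})`, which reduces to FOP at
  `α_HOP = 1`);
* **directed exploration** — none, a *bandit counter* (how many of the
  other second-stage options were sampled since this one was last chosen,
  0–3), or a *trial counter* (`max(0, ln t)` trials since last sampled),
  summed per second-stage state and transition-weighted into a first-stage
  bonus scaled by a free weight `φ`.

All variants share a SARSA learner with learning rates `α₁` (stage 1) and
`α₂` (stage 2, also propagating the stage-2 prediction error to stage 1),
forgetting of unchosen values toward the mid-range at rate `α₃`, Bellman
model-based values `Q_MB(a) = Σ_s P(s|a) max_a' Q₂(s, a')`, and SoftMax
choice rules with separate weights `β_MB`, `β_MF`, `β_persev` (stage 1) and
`β₂` (stage 2).

Fitting is hierarchical Bayesian: subject-level parameters are drawn from
group-level Gaussians (`M^x ~ Normal(0, 10)`; `Λ^x ~ Uniform(0, 10)` for
rates, `Uniform(0, 20)` otherwise), rates mapped to (0, 1) by the
standard-normal CDF. Models are compared by PSIS-LOO elpd with the
`|elpd_diff|/se_diff` evidence ratio and WAIC; posterior predictive checks
simulate full datasets from posterior draws and compare stay-probability
patterns; a one-step-ahead prediction accuracy scores first-stage choices.

A built-in task generator simulates both task variants and cohorts of
agents from any model variant under known group-level parameters, so the
entire chain — generation, fitting, comparison, predictive checks, and the
model-agnostic stay regressions — is testable end-to-end without any
empirical data.

## Worked example

```python
from twostep import HybridTwoStepModel, SamplerConfig, TaskConfig, compare_results
from twostep.task import default_cohort

task = TaskConfig("magnitude")                    # 300 trials, walks in [0, 100]
data, truth = default_cohort(task, "q_hop", n_subjects=10, seed=7)

results = {}
for name in ("q_fop", "q_hop"):
    model = HybridTwoStepModel(data, name, task)
    results[name] = model.fit(sampler=SamplerConfig.test_scale(seed=1))

print(results["q_hop"].summary())
table = compare_results(list(results.values()))
print(table[["model", "elpd", "elpd_diff", "se_diff", "evidence_ratio", "waic"]]
      .round(2).to_string(index=False))
per_subject, summary = results["q_hop"].prediction_accuracy()
print(summary.round(3).to_string(index=False))
```

prints (abridged):

```
Hybrid two-step model: q_hop
subjects: 10, trials: 3000 (3000 valid)
MCMC: 4 chains x 1500 iterations (1000 warm-up), 2000 retained draws
max split R-hat: 1.097 (converged)

Group-level posterior (rates on (0,1) scale):
  parameter   mean  median    sd  hdi_2_5  hdi_97_5  rhat
     alpha2  0.709   0.701 0.091    0.543     0.907 1.052
  alpha_hop  0.529   0.519 0.102    0.331     0.733 1.006
    beta_mb 11.555  11.488 1.500    8.737    14.255 1.024
beta_persev  1.376   1.379 0.184    1.032     1.741 1.004
      beta2 10.619  10.575 0.675    9.281    12.025 1.010

model    elpd  elpd_diff  se_diff  evidence_ratio    waic
q_hop -1830.7       0.00     0.00             NaN 3661.07
q_fop -1840.4       9.71     6.93             1.4 3680.30

  min   p25  median  mean   p75   max
0.732 0.799   0.828 0.852 0.897 0.995
```

Reading the output: the cohort was generated from the higher-order
perseveration model with a habit step size near 0.5, and the fit recovers
the group-level parameters (`alpha_hop` ≈ 0.53, `beta_mb` ≈ 11.6 against
generating means of 0.57 and 10.6). LOO ranks the generating `q_hop`
variant above `q_fop` by ~10 elpd units (evidence ratio 1.4), and the
winning model predicts held-in first-stage choices with a mean one-step
accuracy of 0.85.

The same stages are available from the shell:

```bash
twostep simulate --variant magnitude --model q_hop --subjects 20 --seed 1 \
    --params params.json --out run/
twostep fit --model q_hop --data run/data.csv --chains 4 --iter 1500 --warmup 1000 \
    --seed 1 --out run/fit_q_hop
twostep compare --fits run/fit_q_hop --fits run/fit_q_fop --out run/comparison.csv
```

## Layout

| module | contents |
|---|---|
| `twostep.task` | task configs, outcome random walks, transition sampling, agent and cohort simulation |
| `twostep.variants` | the six model variants and parameter sets |
| `twostep.latent` / `twostep._core` | latent-state updates and choice rules (reference Python and numba kernels) |
| `twostep.likelihood` | sequence log-likelihood, one-step-ahead choice probabilities |
| `twostep.inference` | hierarchical MCMC, MAP mode, split R-hat, posterior containers |
| `twostep.comparison` | PSIS-LOO, WAIC, comparison table, evidence ratio |
| `twostep.agnostic` | reward coding, stay tables, difference scores, stay regressions, correlations |
| `twostep.ppc` | posterior predictive simulation, stay summaries, prediction accuracy |
| `twostep.model` | `HybridTwoStepModel` / results front end |
| `twostep.io`, `twostep.pipeline`, `twostep.cli` | CSV schema, filtering, end-to-end pipeline, CLI |

See `docs/methods.md` for the model equations, sampler design, synthetic-
cohort conditions and known limitations.
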