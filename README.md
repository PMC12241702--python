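# metaflex

Metacognitive efficiency and cognitive flexibility from behavioural data:
type-2 signal detection (meta-d′ / M-ratio) for confidence-rated two-choice
experiments, reversal-learning scoring for a rule-switching trading game,
the group-level inference layer that relates them, and a synthetic-cohort
generator for end-to-end testing when the participant data are not
available.

## Who this is for

Researchers in computational psychiatry and behavioural psychometrics who
measure *metacognition* — how well confidence tracks accuracy — and
*cognitive flexibility* — how fast behaviour adapts when hidden rules
change — and want a tested, reproducible implementation of the standard
analysis chain: per-subject SDT fits, hierarchical group estimation,
learning-speed scoring with censoring, and the ANOVA/rank-correlation
battery on top.

## The models

**Type-1 SDT.** For a two-choice task (here: are two 3-D shapes identical
or different?), equal-variance Gaussian SDT gives sensitivity and bias
from the hit rate and false-alarm rate:

    d′ = z(HR) − z(FAR),    c = −(z(HR) + z(FAR)) / 2

**Meta-d′.** Confidence ratings (1–4) define a type-2 task: discriminating
one's own correct from incorrect responses. meta-d′ is the type-1
sensitivity an ideal observer would need to produce the observed type-2
performance; it is estimated by maximum likelihood over the
response-conditional confidence multinomials. Metacognitive *efficiency*
is the M-ratio meta-d′/d′ (comparable across subjects of different
ability); metacognitive *bias* is mean confidence, with values above the
scale midpoint read as over-confidence. A hierarchical Bayesian variant
pools subjects through log M-ratio ~ Normal(μ_g, σ_g), the estimator of
choice at low trial counts, with MCMC diagnostics (R-hat, ESS) reported.

**Cognitive flexibility.** In the trading game, players sell minerals to
aliens under a hidden payoff matrix (5/10/20 coins) that reverses after
trial 48 (5 ↔ 20). Learning is complete at the trial that ends three
consecutive 20-coin transactions (mineral-4 fillers are transparent) with
no later pair of consecutive 5-coin transactions; the trial count to reach
that point before / after the reversal is the learning / re-learning
speed. Subjects who never qualify are censored, never silently numeric.

**Inference.** Two-way group × region ANOVA (Type-III, partial η²), the
split-plot ANOVA for confidence on correct vs incorrect responses,
Spearman and partial Spearman correlations with Fisher z, two-sample
correlation comparison, and design sensitivity (minimal detectable
Cohen's f).

## Worked example

```python
from metaflex import (SubjectParams, simulate_confidence_trials, MetaDModel,
                      build_schedule, simulate_trading_agent, score_game)

p = SubjectParams("S001", "ASD", "A", d_prime_true=1.3, m_ratio_true=0.6,
                  bias_true=3.4, learning_rate=0.7, explore_rate=0.05,
                  switch_threshold=4, seed=7)

fit = MetaDModel.from_trials(simulate_confidence_trials(p, n_trials=1000)).fit()
print(fit.summary())

m = score_game(simulate_trading_agent(p, build_schedule(seed=11)))
print("learning_speed   ", m.learning_speed)
print("relearning_speed ", m.relearning_speed)
```

prints

```
Meta-d' model (response-conditional multinomial MLE)
----------------------------------------------------
n trials                1000
d'                    1.3365
criterion c          -0.0125
meta-d'               0.9590
M-ratio               0.7175
log-likelihood     -874.3384
converged               True
type-2 criteria   [-0.407, -0.276, -0.139, 0.124, 0.290, 0.418]
learning_speed    6
relearning_speed  16
```

The subject's estimated d′ (1.34) and M-ratio (0.72, true 0.6) come from
1000 simulated trials; at the experiment's 72 trials per subject the MLE
is far noisier, which is why group questions go through the hierarchical
model. The game metrics say this agent first met the learning criterion on
trial 6 and, with a switch threshold of 4 betrayals, re-met it 16 trials
after the reversal.

The full pipeline — simulate (or ingest CSVs), fit every subject, score
every game, run the statistics battery, write `fits.csv`,
`game_metrics.csv`, `stats_report.csv` and a run log — is one call or one
command:

```sh
metaflex run-all --seed 42 --out results/demo
```

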