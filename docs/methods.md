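# Methods

## The measurement problem

Two constructs are measured per subject and then related at the group
level:

* **Metacognitive efficiency** from a confidence-rated mental-rotation
  task: 72 two-choice trials (36 identical-pair, 36 different-pair), each
  followed by a confidence rating on a 1–4 scale.
* **Cognitive flexibility** from a trading game: 68 trials of selling four
  minerals to three alien species under a hidden payoff matrix whose 5- and
  20-coin contingencies swap after trial 48. Flexibility is the speed of
  re-learning the optimal mapping after the reversal.

The participant data behind these analyses are available only on request,
so the package ships a synthetic-cohort generator that reproduces the
study's design frame and lets every stage be tested end to end.

## Type-1 and type-2 signal detection

Responses are modelled with equal-variance Gaussian SDT. With hit rate HR
(identical pairs called identical) and false-alarm rate FAR (different
pairs called identical),

    d' = z(HR) − z(FAR),    c = −(z(HR) + z(FAR)) / 2.

Rates of exactly 0 or 1 are moved inward by 1/(2N) for the stimulus class
with N trials — the standard correction; the data cannot distinguish a
perfect subject from a very good one at these trial counts.

Metacognitive sensitivity is **meta-d′** (Maniscalco & Lau's
response-conditional formulation): the type-1 sensitivity an SDT-ideal
observer would need for its confidence to discriminate its own correct
from incorrect responses as well as the observed ratings do. The meta
level re-uses the type-1 criterion scaled by meta-d′/d′, and places
`n_levels − 1` type-2 criteria on each side of it. Confidence-bin
probabilities are normal-CDF differences renormalised within each
(stimulus, response) cell, and the likelihood is the product of the four
resulting multinomials. Numerical choices:

* criteria are parameterised as cumulative exponentials of free
  parameters, which enforces strict monotone ordering on each side of the
  scaled criterion;
* bin probabilities are floored at 1e-10 inside the log — no count padding
  is ever applied to the data;
* the MLE runs L-BFGS-B from five deterministic starting points
  (meta-d′ at 0.1, 0.5d′, d′, 1.5d′, −0.5d′) with ftol 1e-8, keeping the
  best likelihood; `fit_grid` provides an exhaustive profile scan over
  meta-d′ ∈ [0, 5] in steps of 0.01 used to cross-check the optimizer;
* d′ = 0 makes the M-ratio undefined; the fit is returned flagged, never
  silently numeric.

**Metacognitive efficiency** is the M-ratio meta-d′/d′, which discounts
metacognitive sensitivity for task performance; **metacognitive bias** is
the mean confidence over all trials, with values above the scale midpoint
(2.5 on a 1–4 scale) read as over-confidence. Bias uses only the
confidence column, so it is invariant to correctness relabelling.

## Hierarchical Bayesian M-ratio

At 72 trials the per-subject MLE of the M-ratio is heavily dispersed
(simulations at the study's own operating point — d′ ≈ 1.2–1.4, mean
confidence 3.5 — show a subject-level SD around 0.6, with occasional
boundary escapes). The hierarchical model pools subjects instead:

    log M_i ~ Normal(μ_g, σ_g),  μ_g ~ Normal(0, 1),  σ_g ~ HalfNormal(1)

with the subject likelihood evaluated at meta-d′ = M_i · d′_i after
profiling out the type-2 criteria (each subject's profile log-likelihood is
precomputed on a 41-point grid over meta-d′ ∈ [0, 6], spline-resampled to a
step of 0.005 and interpolated inside the sampler; beyond the grid the
terminal slope is continued linearly). Type-1 d′ and c are treated as
fixed per-subject quantities, the usual two-stage meta-d′ practice.

Sampling is blocked random-walk Metropolis: subject effects are updated
coordinate-wise (they are conditionally independent given the group
parameters), the pair (μ, log σ) jointly, with acceptance-rate adaptation
toward 0.44/0.30 during warm-up only. Defaults are 4 chains × 2000 draws
after 1000 warm-up iterations; split-R-hat and effective sample size are
computed with arviz for every parameter block, and any R-hat above 1.1
flags the result as non-converged. Groups are fitted independently; the
between-group contrast is the paired-draw difference of the two μ
posteriors with a central 95% interval.

Two pathways feed subject-level M-ratios into the downstream ANOVA: the
per-subject MLE (default) and the hierarchical posterior means (optional
flag). The two differ in a way that matters: shrinkage collapses
within-group spread, so an ANOVA on posterior means is strongly
anticonservative — it produces the very large F statistics characteristic
of this estimation style, and occasionally a "significant" difference in
the direction opposite to the generating one. The power studies below
report both the raw and the direction-consistent detection rates.

## The trading game and flexibility scoring

The payoff matrix (aliens × minerals, coins):

    alien 1:  5 10 20 10
    alien 2: 20  5 10 10
    alien 3: 10 20  5 10

Minerals 1–3 each pay {5, 10, 20} across the aliens; mineral 4 pays 10 to
everyone and exists only to probe alien preference. The schedule presents
each mineral 12 times in random order (48 trials), then reverses the rules
(every 5 becomes 20 and vice versa; 10s unchanged) and presents each
mineral 5 more times. The randomised order is drawn once per seed and
shared by all subjects, mirroring the experiment's frozen order.

Learning within a phase is complete at the trial satisfying both:
(1) it ends a run of three consecutive 20-coin transactions among trials
where 20 coins were obtainable — mineral-4 trials neither extend nor break
the run; and (2) no two consecutive 5-coin transactions (again skipping
mineral-4 trials, which cannot pay 5) occur later in the phase. "Later"
runs to the end of the phase (trial 48 or 68); the criterion statement
gives no other horizon. The reported learning point is, by default, the
position of the run-completing trial counted over all trials of the phase
including mineral-4 fillers ("completion" convention); the first-trial
convention ("run_start") is available, as the underlying description
admits both readings. Re-learning speed is the same quantity on trials
49–68 against the reversed matrix, counted from trial 49. Subjects who
never qualify are censored — recorded as missing with the phase length,
never silently numeric. For rank-based analyses, censored speeds are, by
default, capped at phase length + 1 (worst rank); exclusion is available
by configuration.

## Synthetic cohorts

The generator inverts the measurement models:

* **Confidence trials** — responses from equal-variance SDT at the
  subject's true d′ (criterion 0 by default); confidence from the meta
  model's response-conditional bin probabilities at
  meta-d′ = M-ratio × d′. Type-2 criteria sit at equally spaced offsets
  (0.5, 1.0, 1.5 z-units) around the scaled criterion, scaled by a single
  spread parameter solved by bisection so that expected mean confidence
  equals the subject's true bias. An unreachable bias raises.
* **Trading agent** — a value tracker over (mineral, alien) pairs with
  optimistic initialisation and an epsilon-greedy rule while learning; the
  first 20-coin outcome for a mineral commits the agent to that alien
  (win-stay). After the reversal, committed choices pay 5; the agent
  abandons its whole mapping only after `switch_threshold` consecutive
  betrayals of committed choices (mineral-4 trials are transparent), then
  relearns knowing only that the just-betrayed pairing is bad. The
  threshold is the perseveration knob: re-learning speed is monotone in
  it, and an infinite threshold yields a censored perseverator.
* **Cohort assembly** — two groups (ASD/TD) × two regions with the study's
  33 + 33 frame (18 and 15 subjects per region). Defaults encode the
  study's reported pattern and are not tuned per run: d′ ~ N(1.2, 0.35)
  for ASD and N(1.4, 0.35) for TD (the TD accuracy advantage); true
  M-ratio ~ N(0.6, 0.1) for ASD and N(0.4, 0.1) for TD (the reported
  hierarchical group estimates are ≈ 0.62 and ≈ 0.43, and their huge group
  F implies a small between-subject spread); bias from a truncated
  N(3.5, 0.35) on [2.55, 3.95] (group mean confidence 3.5; no subject
  below the 2.5 midpoint); agent learning rate U(0.4, 0.9) and exploration
  U(0.02, 0.12). A Gaussian copula couples true bias to the switch
  threshold (8 levels — longer perseveration is unobservable in a 20-trial
  phase). Because re-learning speed is only a noisy monotone image of the
  threshold, the copula correlation is amplified by a fixed calibration
  constant (1/0.65) so that the realised Spearman(bias, re-learning)
  approximates the requested target; the calibration was set once from a
  measured attenuation curve and realises −0.51 ± 0.12 at a −0.5 target
  (and exactly 0 at a 0 target). The association is generated as a
  correlation, not a mechanism — matching how it is reported. All
  randomness flows from one root seed via `SeedSequence` stream splitting;
  a truth table of generating parameters accompanies every cohort.

What the generator does **not** emulate: response-time structure, learning
within the rotation task, criterion drift, sex composition, or any causal
mechanism connecting overconfidence to perseveration. Passing recovery
tests therefore show that the pipeline measures what the generative models
encode, not that the psychological claims are true.

## Inference layer

* Two-way (group × region) ANOVA with Type-III sums of squares via
  sum-coded OLS; partial η² = SS_effect / (SS_effect + SS_error); optional
  covariate (AN(C)OVA for re-learning on learning speed).
* The mixed (split-plot) ANOVA for the accuracy-conditioned confidence
  means uses the classical decomposition, exact for a two-level within
  factor: between effects from subject means, within effects from
  difference scores (subjects lacking one level — e.g. error-free
  subjects — are excluded with a warning).
* Spearman correlations use average ranks with t-approximation p-values
  (appropriate at n ≈ 33–66); a permutation option exists. Partial
  Spearman is the first-order Pearson partial correlation on ranks, p from
  t with n − 3 df.
* Fisher z = atanh(ρ); two independent correlations are compared with
  Z = (z₁ − z₂) / √(1/(n₁−3) + 1/(n₂−3)) and a one-sided p (the worked
  values 1.44 → 0.075 and 0.481 → 0.315 are one-sided normal tails).
* Design sensitivity: the minimal Cohen's f at which a factorial effect
  reaches target power (default 0.80) under the noncentral-F distribution
  with λ = f²·N, found by bracketing and Brent root-finding. For the
  study frame (N = 66, 2 × 2 cells) it gives f = 0.350. Note f = 0.35
  corresponds to η²ₚ = f²/(1+f²) ≈ 0.11, not .06 as sometimes quoted with
  it; the package reports f and leaves the conversion to the reader.

## Problem sizes and seeds

Recovery and calibration studies are sized to make their points at
workstation scale: 20-table optimizer-vs-grid agreement, 300 fits of
1000-trial subjects for recovery (100 per true meta-d′ level, simulated at
mid-scale confidence so the sample median is a stable estimate of the
engine's accuracy), 1000 random sequences for the detector
equivalence, 20 replications of the full 66-subject cohort for each power
study, and 500 replications for ANOVA Type-I calibration. Every stochastic
routine takes an explicit seed and is reproducible bit for bit (MCMC
included).

## Known limitations

* With 72 trials and mean confidence near 3.5, the information per subject
  about meta-d′ is small. Group-mean posteriors have SD ≈ 0.2 on the log
  scale, so the posterior contrast between groups at true M-ratios
  0.6 vs 0.4 (log contrast 0.405) frequently includes zero — interval
  exclusion is not a reliable detector at this design size. The ANOVA on
  shrunken posterior means does detect the difference reliably, but its F
  statistic is anticonservative (see above); both detection rates are
  reported.
* The learning-speed convention (completion vs run-start, mineral-4 trials
  in or out of the index) is configurable because the criterion prose
  admits both; defaults are documented above.
* The agent is a scoring device, not a cognitive model of autism; the
  copula coupling is correlational by construction.
* Hierarchical priors are the package's defaults, documented above; they
  are not claimed to replicate any particular published posterior.
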