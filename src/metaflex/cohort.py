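"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's participant data are request-only, so every pipeline stage is
exercised on simulated subjects instead.  Three generators are provided:

``simulate_confidence_trials``
    The generative inverse of the meta-d' model: type-1 responses from
    equal-variance SDT at the subject's true d', confidence drawn from the
    response-conditional bin probabilities at meta_d = M-ratio x d', with
    type-2 criteria positioned so the expected mean confidence equals the
    subject's true metacognitive bias.

``simulate_trading_agent``
    A value-tracking player of the trading game.  It learns (mineral,
    alien) values with a per-trial update weight and optimistic
    initialisation, commits to an alien once it pays the 20-coin maximum
    (win-stay), and — after the hidden reversal — abandons its committed
    mapping only after ``switch_threshold`` consecutive sub-maximal
    outcomes on committed choices.  The threshold is the perseveration
    knob that turns into re-learning speed downstream.

``simulate_cohort``
    Draws per-subject parameters for a two-group (ASD/TD), two-region
    cohort.  A Gaussian copula couples the true confidence bias to the
    agent's switch threshold so that the realised rank correlation between
    bias and re-learning speed approximates a target value; the association
    is treated as a correlation, not a mechanism, because that is all the
    downstream analyses measure.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` stream splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .metad import response_conditional_probs
from .sdt import NOISE, SIGNAL, TrialRecord
from .trading import (
    RewardMatrix,
    TransactionRecord,
    TrialScheduleEntry,
    build_reward_matrix,
    build_schedule,
    reverse_rules,
)

GROUPS = ("ASD", "TD")
REGIONS = ("A", "B")


@dataclass
class SubjectParams:
    """Generating ("true") parameters for one synthetic subject."""

    subject_id: str
    group: str
    region: str
    d_prime_true: float
    m_ratio_true: float
    bias_true: float            # target mean confidence, in rating units
    learning_rate: float        # per-trial value-update weight
    explore_rate: float         # probability of a random choice while learning
    switch_threshold: float     # consecutive sub-maximal rewards before strategy abandonment
    seed: int

    def __post_init__(self) -> None:
        if self.m_ratio_true < 0:
            raise ValueError("m_ratio_true must be non-negative")
        if not (1.0 <= self.bias_true <= 4.0):
            raise ValueError("bias_true must lie in [1, 4]")
        if self.switch_threshold < 1:
            raise ValueError("switch_threshold must be >= 1")


@dataclass
class CohortSpec:
    """Design of a synthetic two-group, two-region cohort.

    ``n_per_cell`` gives the subjects per region within each group; the
    default (18, 15) reproduces the study frame of 33 subjects per group
    split over two recruitment regions.  Group means for d' and M-ratio
    default to the study's pattern: the TD group more sensitive
    (higher d') but less metacognitively efficient (lower M-ratio).
    """

    n_per_cell: int | tuple[int, int] = (18, 15)
    correlation_bias_flexibility: float = -0.5
    mean_d_prime: dict = field(default_factory=lambda: {"ASD": 1.2, "TD": 1.4})
    sd_d_prime: float = 0.35
    mean_m_ratio: dict = field(default_factory=lambda: {"ASD": 0.6, "TD": 0.4})
    sd_m_ratio: float = 0.1
    bias_mean: float = 3.5
    bias_sd: float = 0.35
    bias_range: tuple[float, float] = (2.55, 3.95)
    n_rotation_trials: int = 72
    n_levels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.correlation_bias_flexibility <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        if min(self.cell_sizes) < 2:
            raise ValueError("need at least 2 subjects per cell")

    @property
    def cell_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_cell, int):
            return (self.n_per_cell, self.n_per_cell)
        return tuple(self.n_per_cell)  # type: ignore[return-value]


# ---- confidence-task generator ------------------------------------------

_BASE_OFFSETS_SCALE = 0.5  # type-2 criteria start 0.5 z-units apart


def _criteria_for_bias(
    d_prime: float,
    m_ratio: float,
    bias: float,
    criterion: float,
    n_levels: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Place symmetric type-2 criteria whose expected mean confidence is ``bias``.

    A single spread parameter scales equally spaced offsets around the
    scaled criterion; shrinking the spread pushes all ratings toward the
    top of the scale.  Solved by bisection; raises if the target is
    unreachable.
    """
    meta_d = m_ratio * d_prime
    c_meta = criterion * m_ratio  # = criterion * meta_d / d_prime
    base = _BASE_OFFSETS_SCALE * np.arange(1, n_levels)
    mu1 = np.array([-d_prime / 2.0, d_prime / 2.0])
    p_ident = 1.0 - norm.cdf(criterion - mu1)  # P(respond "identical" | s)
    levels = np.arange(1, n_levels + 1)

    def mean_conf(theta: float) -> float:
        off = base * np.exp(-theta)
        probs = response_conditional_probs(meta_d, c_meta, c_meta + off, c_meta - off)
        total = 0.0
        for s in (0, 1):
            total += 0.5 * (
                p_ident[s] * np.dot(levels, probs[s, 1])
                + (1 - p_ident[s]) * np.dot(levels, probs[s, 0])
            )
        return total

    lo, hi = -8.0, 8.0
    m_lo, m_hi = mean_conf(lo), mean_conf(hi)
    if not (m_lo + 1e-6 <= bias <= m_hi - 1e-6):
        raise ValueError(
            f"target mean confidence {bias} unreachable with these criteria "
            f"(attainable range [{m_lo:.4f}, {m_hi:.4f}])"
        )
    theta = brentq(lambda t: mean_conf(t) - bias, lo, hi, xtol=1e-10)
    off = base * np.exp(-theta)
    return c_meta + off, c_meta - off, meta_d


def simulate_confidence_trials(
    params: SubjectParams,
    n_trials: int = 72,
    criterion: float = 0.0,
    n_levels: int = 4,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate one subject's confidence-rated mental-rotation session.

    Half the trials show identical pairs, half different pairs, in a
    shuffled order.  Responses follow equal-variance SDT at
    ``d_prime_true``; confidence follows the meta-d' model at
    ``meta_d = m_ratio_true * d_prime_true``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    above, below, meta_d = _criteria_for_bias(
        params.d_prime_true, params.m_ratio_true, params.bias_true,
        criterion, n_levels,
    )
    c_meta = criterion * params.m_ratio_true
    p_conf = response_conditional_probs(meta_d, c_meta, above, below)

    n_signal = n_trials // 2
    stimuli = np.array([1] * n_signal + [0] * (n_trials - n_signal))
    rng.shuffle(stimuli)
    mu1 = np.array([-params.d_prime_true / 2.0, params.d_prime_true / 2.0])
    evidence = rng.normal(mu1[stimuli], 1.0)
    responses = (evidence > criterion).astype(int)

    trials = []
    for s, r in zip(stimuli, responses):
        conf = rng.choice(n_levels, p=p_conf[s, r] / p_conf[s, r].sum()) + 1
        trials.append(
            TrialRecord(
                subject_id=params.subject_id,
                stimulus=SIGNAL if s else NOISE,
                response=SIGNAL if r else NOISE,
                confidence=int(conf),
            )
        )
    return trials


# ---- trading-game agent --------------------------------------------------

_OPTIMISTIC_VALUE = 20.0


def simulate_trading_agent(
    params: SubjectParams,
    schedule: Sequence[TrialScheduleEntry],
    matrix: RewardMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> list[TransactionRecord]:
    """Play the trading game with a value-tracking, perseverating agent.

    While a mineral is unlearned the agent chooses epsilon-greedily over
    optimistic per-(mineral, alien) value estimates updated with
    ``learning_rate``; the first 20-coin outcome commits it to that alien
    (win-stay).  Committed choices are replayed without further learning.
    After the hidden reversal, committed choices start paying 5;
    ``switch_threshold`` consecutive such betrayals (mineral-4 trials are
    transparent) are needed before the agent discards the whole mapping and
    relearns, knowing only that the just-betrayed pairing is bad.  An
    infinite threshold produces a perseverative player whose re-learning is
    censored.
    """
    if matrix is None:
        matrix = build_reward_matrix()
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    reversed_matrix = reverse_rules(matrix)

    q = np.full((4, 3), _OPTIMISTIC_VALUE)  # mineral x alien value estimates
    committed = np.full(4, -1)  # committed alien per mineral, -1 = none
    submax = 0  # consecutive betrayals of committed choices

    records = []
    for entry in schedule:
        active = matrix if entry.phase == "pre_reversal" else reversed_matrix
        m = entry.mineral - 1
        if committed[m] >= 0:
            alien = int(committed[m])
        elif rng.random() < params.explore_rate:
            alien = int(rng.integers(3))
        else:
            best = np.flatnonzero(q[m] == q[m].max())
            alien = int(rng.choice(best))
        reward = active.reward(alien + 1, entry.mineral)
        records.append(
            TransactionRecord(
                trial_index=entry.trial_index,
                mineral=entry.mineral,
                chosen_alien=alien + 1,
                reward=reward,
            )
        )
        if entry.mineral == 4:
            continue  # mineral 4 carries no information about the rules
        if committed[m] >= 0:
            # a committed mineral should keep paying 20; count consecutive
            # betrayals, abandon the whole mapping at the threshold
            if reward < 20:
                submax += 1
                if submax >= params.switch_threshold:
                    committed[:] = -1
                    q[:] = _OPTIMISTIC_VALUE
                    # the just-betrayed choices are known to be bad now
                    q[m, alien] = reward
                    submax = 0
            else:
                submax = 0
        else:
            q[m, alien] += params.learning_rate * (reward - q[m, alien])
            if reward == 20:
                committed[m] = alien  # win-stay: lock in the 20-coin alien
    return records


# ---- cohort assembly -----------------------------------------------------


@dataclass
class CohortData:
    """Simulated cohort: raw tables plus the generating truth."""

    trials: pd.DataFrame
    transactions: pd.DataFrame
    truth: pd.DataFrame
    schedule: pd.DataFrame
    params: list[SubjectParams]


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson correlation giving Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


#: the copula couples bias to the switch threshold, but re-learning speed is
#: only a noisy monotone image of the threshold (discrete levels, re-learning
#: noise, censoring), which shrinks the realised rank correlation by roughly
#: this factor; the coupling is amplified to compensate so that the realised
#: Spearman(bias, re-learning) approximates the requested target.
_COUPLING_ATTENUATION = 0.65


def draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectParams]:
    """Draw per-subject generating parameters for the whole cohort."""
    amplified = np.clip(
        spec.correlation_bias_flexibility / _COUPLING_ATTENUATION, -0.93, 0.93
    )
    r = _spearman_to_pearson(float(amplified))
    cov = np.array([[1.0, r], [r, 1.0]])
    lo, hi = spec.bias_range
    a = (lo - spec.bias_mean) / spec.bias_sd
    b = (hi - spec.bias_mean) / spec.bias_sd

    params: list[SubjectParams] = []
    idx = 0
    for group in GROUPS:
        for region, n_cell in zip(REGIONS, spec.cell_sizes):
            for _ in range(n_cell):
                idx += 1
                z = rng.multivariate_normal([0.0, 0.0], cov)
                u_bias, u_thresh = norm.cdf(z)
                bias = float(
                    truncnorm.ppf(u_bias, a, b, loc=spec.bias_mean, scale=spec.bias_sd)
                )
                # 8 threshold levels: the post-reversal phase has only ~15
                # eligible trials, so longer perseveration is unobservable
                threshold = 1 + int(np.floor(u_thresh * 8))
                d_true = max(0.3, rng.normal(spec.mean_d_prime[group], spec.sd_d_prime))
                mr_true = max(0.05, rng.normal(spec.mean_m_ratio[group], spec.sd_m_ratio))
                params.append(
                    SubjectParams(
                        subject_id=f"S{idx:03d}",
                        group=group,
                        region=region,
                        d_prime_true=float(d_true),
                        m_ratio_true=float(mr_true),
                        bias_true=bias,
                        learning_rate=float(rng.uniform(0.4, 0.9)),
                        explore_rate=float(rng.uniform(0.02, 0.12)),
                        switch_threshold=float(threshold),
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
    return params


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Generate trials, transactions and the truth table for a cohort.

    The trading schedule is drawn once from the root seed and shared by
    every subject, matching the experiment's frozen randomised order.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_params, ss_schedule, ss_subjects = root.spawn(3)
    rng = np.random.default_rng(ss_params)
    params = draw_subject_params(spec, rng)

    schedule = build_schedule(int(np.random.default_rng(ss_schedule).integers(2**31 - 1)))
    matrix = build_reward_matrix()

    trial_rows = []
    tx_rows = []
    subject_streams = ss_subjects.spawn(len(params))
    for p, ss in zip(params, subject_streams):
        srng = np.random.default_rng(ss)
        trials = simulate_confidence_trials(
            p, n_trials=spec.n_rotation_trials, n_levels=spec.n_levels, rng=srng
        )
        for i, t in enumerate(trials):
            trial_rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": p.group,
                    "region": p.region,
                    "trial_index": i + 1,
                    "stimulus": t.stimulus,
                    "response": t.response,
                    "confidence": t.confidence,
                }
            )
        for tx in simulate_trading_agent(p, schedule, matrix, rng=srng):
            tx_rows.append(
                {
                    "subject_id": p.subject_id,
                    "trial_index": tx.trial_index,
                    "mineral": tx.mineral,
                    "alien": tx.chosen_alien,
                    "reward": tx.reward,
                }
            )

    truth = pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "group": p.group,
                "region": p.region,
                "d_prime_true": p.d_prime_true,
                "m_ratio_true": p.m_ratio_true,
                "bias_true": p.bias_true,
                "learning_rate": p.learning_rate,
                "explore_rate": p.explore_rate,
                "switch_threshold": p.switch_threshold,
                "seed": p.seed,
            }
            for p in params
        ]
    )
    schedule_df = pd.DataFrame(
        [
            {"trial_index": e.trial_index, "mineral": e.mineral, "phase": e.phase}
            for e in schedule
        ]
    )
    return CohortData(
        trials=pd.DataFrame(trial_rows),
        transactions=pd.DataFrame(tx_rows),
        truth=truth,
        schedule=schedule_df,
        params=params,
    )
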