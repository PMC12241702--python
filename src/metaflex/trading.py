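"""The alien trading game: reward rules, schedule, and flexibility scoring.

Players sell four minerals to three alien species.  Each (alien, mineral)
pair pays 5, 10 or 20 coins; for minerals 1-3 the three aliens' payoffs are
a permutation of {5, 10, 20}, while mineral 4 pays 10 to everyone (it only
probes alien preference).  After 48 trials the 5- and 20-coin contingencies
swap and the player must re-learn the optimal pairing without being told.

Learning within a phase is complete when
(1) the player earns the 20-coin maximum on three consecutive transactions
    among trials where 20 coins were obtainable (mineral-4 trials neither
    extend nor break such a run), and
(2) no two consecutive minimum-reward (5-coin) transactions occur later in
    the phase (again skipping mineral-4 trials, which can never pay 5).

The trial count to reach that point pre-reversal is the learning speed; the
count from the first post-reversal trial is the re-learning speed, the
operational measure of cognitive flexibility.  Subjects who never qualify
are censored, never silently numeric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

N_TRIALS = 68
N_PRE = 48
N_POST = N_TRIALS - N_PRE
PRE_REPEATS = 12   # presentations of each mineral before reversal
POST_REPEATS = 5   # presentations after reversal
REWARDS = (5, 10, 20)

#: payoff[alien - 1][mineral - 1], coins
_BASE_MATRIX = np.array(
    [
        [5, 10, 20, 10],
        [20, 5, 10, 10],
        [10, 20, 5, 10],
    ]
)


@dataclass(frozen=True)
class RewardMatrix:
    """Coins paid by each alien (rows, 1-3) for each mineral (cols, 1-4)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        if v.shape != (3, 4):
            raise ValueError("reward matrix must be 3 aliens x 4 minerals")
        for mineral in range(3):
            if sorted(v[:, mineral]) != [5, 10, 20]:
                raise ValueError(
                    f"mineral {mineral + 1} payoffs must be a permutation of (5, 10, 20)"
                )
        if not (v[:, 3] == 10).all():
            raise ValueError("mineral 4 must pay 10 to every alien")
        object.__setattr__(self, "values", v)

    def reward(self, alien: int, mineral: int) -> int:
        return int(self.values[alien - 1, mineral - 1])

    def max_reward(self, mineral: int) -> int:
        return int(self.values[:, mineral - 1].max())

    def best_alien(self, mineral: int) -> int:
        return int(self.values[:, mineral - 1].argmax()) + 1


def build_reward_matrix() -> RewardMatrix:
    """The game's pre-reversal payoff matrix."""
    return RewardMatrix(_BASE_MATRIX.copy())


def reverse_rules(matrix: RewardMatrix) -> RewardMatrix:
    """Swap every 5 with 20; 10-coin cells are untouched (involution)."""
    v = matrix.values.copy()
    v[matrix.values == 5] = 20
    v[matrix.values == 20] = 5
    return RewardMatrix(v)


@dataclass(frozen=True)
class TrialScheduleEntry:
    trial_index: int  # 1-based over the whole game
    mineral: int
    phase: Literal["pre_reversal", "post_reversal"]


def build_schedule(seed: int) -> list[TrialScheduleEntry]:
    """Randomised mineral order: 12 repeats each pre, 5 each post.

    The order is drawn once from ``seed`` and then treated as frozen — in
    the experiment a single randomised order was shared by all players.
    """
    rng = np.random.default_rng(seed)
    pre = rng.permutation(np.repeat(np.arange(1, 5), PRE_REPEATS))
    post = rng.permutation(np.repeat(np.arange(1, 5), POST_REPEATS))
    entries = [
        TrialScheduleEntry(i + 1, int(m), "pre_reversal") for i, m in enumerate(pre)
    ]
    entries += [
        TrialScheduleEntry(N_PRE + i + 1, int(m), "post_reversal")
        for i, m in enumerate(post)
    ]
    return entries


@dataclass(frozen=True)
class TransactionRecord:
    trial_index: int
    mineral: int
    chosen_alien: int
    reward: int


CENSORED = None  # sentinel for "never learned within the phase"


@dataclass(frozen=True)
class GameMetrics:
    """Learning and re-learning speeds for one subject."""

    learning_speed: int | None       # trials into phase 1; None if censored
    relearning_speed: int | None     # trials counted from trial 49
    learned_pre: bool
    learned_post: bool
    mineral4_choices: tuple[int, int, int]
    n_pre: int = N_PRE
    n_post: int = N_POST


def detect_learning(
    transactions: Sequence[TransactionRecord],
    matrix: RewardMatrix,
    convention: Literal["completion", "run_start"] = "completion",
) -> int | None:
    """Position (1-based, within the phase) at which learning completed.

    Scans for the earliest run of three consecutive 20-coin transactions
    among 20-eligible (non-mineral-4) trials whose remaining phase contains
    no two consecutive 5-coin eligible transactions; mineral-4 trials are
    transparent for both conditions but still occupy positions in the
    index.  Returns ``None`` (censored) if no run qualifies.

    ``convention`` selects whether the reported position is the trial that
    completes the run (default) or the first trial of the run.
    """
    if not transactions:
        raise ValueError("empty transaction list")
    for t in transactions:
        expected = matrix.reward(t.chosen_alien, t.mineral)
        if t.reward != expected:
            raise ValueError(
                f"trial {t.trial_index}: reward {t.reward} inconsistent with "
                f"matrix (expected {expected})"
            )

    # eligible trials: mineral 1-3, where 20 coins were obtainable
    elig = [(pos + 1, t) for pos, t in enumerate(transactions) if t.mineral != 4]
    rewards = [t.reward for _, t in elig]
    positions = [pos for pos, _ in elig]

    for k in range(2, len(elig)):
        if rewards[k - 2] == rewards[k - 1] == rewards[k] == 20:
            # condition (2): no double-5 among eligible trials after the
            # completing transaction
            tail = rewards[k + 1:]
            stable = not any(
                tail[j] == 5 and tail[j + 1] == 5 for j in range(len(tail) - 1)
            )
            if stable:
                return positions[k] if convention == "completion" else positions[k - 2]
    return CENSORED


def mineral4_preference(
    transactions: Iterable[TransactionRecord], margin: float = 3.0
) -> tuple[tuple[int, int, int], bool]:
    """Counts of mineral-4 sales per alien and a preference flag.

    A preference is flagged when the most-chosen alien exceeds the uniform
    expectation (one third of mineral-4 trials) by more than ``margin``.
    """
    counts = [0, 0, 0]
    for t in transactions:
        if t.mineral == 4:
            counts[t.chosen_alien - 1] += 1
    total = sum(counts)
    flagged = total > 0 and max(counts) > total / 3 + margin
    return (counts[0], counts[1], counts[2]), flagged


def score_game(
    transactions: Sequence[TransactionRecord],
    matrix: RewardMatrix | None = None,
    convention: Literal["completion", "run_start"] = "completion",
) -> GameMetrics:
    """Score one subject's full 68-trial game.

    Phase 1 (trials 1-48) is scored against ``matrix``; phase 2 (49-68)
    against its 5<->20 reversal, with positions counted from trial 49.
    """
    if matrix is None:
        matrix = build_reward_matrix()
    txs = sorted(transactions, key=lambda t: t.trial_index)
    indices = [t.trial_index for t in txs]
    expected = list(range(1, N_TRIALS + 1))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        extra = sorted(set(indices) - set(expected))
        raise ValueError(
            f"need trials 1..{N_TRIALS}: missing {missing}, unexpected {extra}"
        )
    pre = txs[:N_PRE]
    post = txs[N_PRE:]
    learn = detect_learning(pre, matrix, convention=convention)
    relearn = detect_learning(post, reverse_rules(matrix), convention=convention)
    m4, _ = mineral4_preference(txs)
    return GameMetrics(
        learning_speed=learn,
        relearning_speed=relearn,
        learned_pre=learn is not None,
        learned_post=relearn is not None,
        mineral4_choices=m4,
    )


# ---- CSV interfaces ------------------------------------------------------


def transactions_from_frame(df: pd.DataFrame) -> dict[str, list[TransactionRecord]]:
    """Group a transactions table into per-subject ordered records."""
    required = {"subject_id", "trial_index", "mineral", "alien", "reward"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transactions table missing columns: {sorted(missing)}")
    out: dict[str, list[TransactionRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            TransactionRecord(
                trial_index=int(row.trial_index),
                mineral=int(row.mineral),
                chosen_alien=int(row.alien),
                reward=int(row.reward),
            )
        )
    for recs in out.values():
        recs.sort(key=lambda t: t.trial_index)
    return out


def metrics_to_frame(metrics: dict[str, GameMetrics]) -> pd.DataFrame:
    """Per-subject metrics table; censored speeds become empty cells."""
    rows = []
    for sid, m in metrics.items():
        rows.append(
            {
                "subject_id": sid,
                "learning_speed": m.learning_speed,
                "relearning_speed": m.relearning_speed,
                "learned_pre": m.learned_pre,
                "learned_post": m.learned_post,
                "mineral4_alien1": m.mineral4_choices[0],
                "mineral4_alien2": m.mineral4_choices[1],
                "mineral4_alien3": m.mineral4_choices[2],
            }
        )
    return pd.DataFrame(rows)
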