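import numpy as np
import pytest

from metaflex.sdt import TrialRecord
from metaflex.trading import TransactionRecord, build_reward_matrix


def make_trial(stimulus, response, confidence, subject="S001"):
    return TrialRecord(
        subject_id=subject, stimulus=stimulus, response=response,
        confidence=confidence,
    )


@pytest.fixture
def perfect_trials():
    """72 trials, all correct: 36 identical, 36 different, confidence 4."""
    return (
        [make_trial("identical", "identical", 4) for _ in range(36)]
        + [make_trial("different", "different", 4) for _ in range(36)]
    )


# reward lookup helpers: (mineral, alien) pairs paying a given amount under
# the pre-reversal matrix: alien1/mineral1 -> 5, alien1/mineral2 -> 10,
# alien1/mineral3 -> 20, any alien/mineral4 -> 10
_PAY = {5: (1, 1), 10: (2, 1), 20: (3, 1)}


def tx_sequence(spec):
    """Build matrix-consistent transactions from a compact spec list.

    Each element is either a reward in {5, 10, 20} (an eligible mineral-1..3
    trial paying that much) or the string "m4" for a mineral-4 filler trial.
    """
    matrix = build_reward_matrix()
    out = []
    for i, item in enumerate(spec):
        if item == "m4":
            mineral, alien = 4, 2
        else:
            mineral, alien = _PAY[item]
        out.append(
            TransactionRecord(
                trial_index=i + 1, mineral=mineral, chosen_alien=alien,
                reward=matrix.reward(alien, mineral),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
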