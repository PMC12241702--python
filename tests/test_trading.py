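"""Reward rules, schedule construction, and the learning-point detector."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaflex.trading import (
    build_reward_matrix,
    build_schedule,
    detect_learning,
    mineral4_preference,
    reverse_rules,
    score_game,
    transactions_from_frame,

)
from metaflex.validation import (
    random_transaction_sequence,
    reference_learning_scan,
)

from conftest import tx_sequence


class TestRewardMatrix:
    def test_printed_payoffs(self):
        m = build_reward_matrix()
        assert m.reward(1, 3) == 20
        assert m.reward(3, 4) == 10
        assert m.reward(1, 1) == 5
        assert m.reward(2, 1) == 20

    def test_minerals_one_to_three_offer_all_three_amounts(self):
        m = build_reward_matrix()
        for mineral in (1, 2, 3):
            assert sorted(m.values[:, mineral - 1]) == [5, 10, 20]

    def test_reversal_swaps_extremes_and_fixes_tens(self):
        m = build_reward_matrix()
        r = reverse_rules(m)
        assert r.reward(1, 1) == 20          # 5 -> 20
        assert r.reward(1, 3) == 5           # 20 -> 5
        assert r.reward(1, 4) == 10          # 10 stays
        np.testing.assert_array_equal(reverse_rules(r).values, m.values)

    def test_reversal_preserves_column_structure(self):
        r = reverse_rules(build_reward_matrix())
        for mineral in (1, 2, 3):
            assert sorted(r.values[:, mineral - 1]) == [5, 10, 20]
        assert (r.values[:, 3] == 10).all()


class TestSchedule:
    def test_structure(self):
        sched = build_schedule(seed=0)
        assert len(sched) == 68
        pre = [e for e in sched if e.phase == "pre_reversal"]
        post = [e for e in sched if e.phase == "post_reversal"]
        assert len(pre) == 48
        for mineral in (1, 2, 3, 4):
            assert sum(e.mineral == mineral for e in pre) == 12
            assert sum(e.mineral == mineral for e in post) == 5
        assert [e.trial_index for e in sched] == list(range(1, 69))

    def test_frozen_under_seed(self):
        assert build_schedule(7) == build_schedule(7)
        assert build_schedule(7) != build_schedule(8)


class TestDetectLearning:
    def test_immediate_learner(self):
        txs = tx_sequence([20, 20, 20, 10, 10])
        assert detect_learning(txs, build_reward_matrix()) == 3

    def test_mineral4_does_not_interrupt_the_run(self):
        txs = tx_sequence([20, "m4", 20, 20])
        assert detect_learning(txs, build_reward_matrix()) == 4

    def test_later_double_five_invalidates_the_early_run(self):
        txs = tx_sequence([20, 20, 20, 10, 5, 5, 10, 20, 20, 20])
        assert detect_learning(txs, build_reward_matrix()) == 10

    def test_run_start_convention(self):
        txs = tx_sequence([10, 20, "m4", 20, 20])
        assert detect_learning(txs, build_reward_matrix(), convention="run_start") == 2
        assert detect_learning(txs, build_reward_matrix()) == 5

    def test_mineral4_pair_is_not_a_double_five(self):
        txs = tx_sequence([20, 20, 20, 5, "m4", 5, 10])
        # the two 5s are separated by a mineral-4 trial in the index but are
        # consecutive among eligible trials: the run is invalidated
        assert detect_learning(txs, build_reward_matrix()) is None

    def test_no_qualifying_run_is_censored(self):
        txs = tx_sequence([10, 20, 20, 5, 10])
        assert detect_learning(txs, build_reward_matrix()) is None

    def test_inconsistent_reward_is_an_error(self):
        from metaflex.trading import TransactionRecord

        txs = tx_sequence([20, 20, 20])
        txs[1] = TransactionRecord(2, txs[1].mineral, txs[1].chosen_alien, 5)
        with pytest.raises(ValueError, match="inconsistent"):
            detect_learning(txs, build_reward_matrix())

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            detect_learning([], build_reward_matrix())

    def test_matches_reference_scan_on_random_sequences(self, rng):
        matrix = build_reward_matrix()
        for _ in range(300):
            txs = random_transaction_sequence(rng, matrix, int(rng.integers(5, 40)))
            for convention in ("completion", "run_start"):
                assert detect_learning(txs, matrix, convention=convention) == \
                    reference_learning_scan(txs, matrix, convention=convention)

    @given(st.lists(st.sampled_from([5, 10, 20, "m4"]), min_size=3, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_reference_equivalence_property(self, spec):
        txs = tx_sequence(spec)
        m = build_reward_matrix()
        assert detect_learning(txs, m) == reference_learning_scan(txs, m)

    def test_terminal_double_five_invalidates_any_run(self):
        base = [20, 20, 20, 10]
        assert detect_learning(tx_sequence(base), build_reward_matrix()) == 3
        extended = tx_sequence(base + [5, 5])
        assert detect_learning(extended, build_reward_matrix()) is None


class TestScoreGame:
    def _optimal_transactions(self):
        sched = build_schedule(seed=3)
        m = build_reward_matrix()
        rev = reverse_rules(m)
        from metaflex.trading import TransactionRecord

        txs = []
        for e in sched:
            mat = m if e.phase == "pre_reversal" else rev
            alien = mat.best_alien(e.mineral)
            txs.append(
                TransactionRecord(e.trial_index, e.mineral, alien,
                                  mat.reward(alien, e.mineral))
            )
        return txs

    def test_optimal_agent_learns_at_third_eligible_trial(self):
        txs = self._optimal_transactions()
        metrics = score_game(txs)
        sched = build_schedule(seed=3)
        elig_pre = [e.trial_index for e in sched[:48] if e.mineral != 4]
        elig_post = [e.trial_index - 48 for e in sched[48:] if e.mineral != 4]
        assert metrics.learning_speed == elig_pre[2]
        assert metrics.relearning_speed == elig_post[2]
        assert metrics.learned_pre and metrics.learned_post

    def test_perseverative_agent_is_censored_after_reversal(self):
        m = build_reward_matrix()
        from metaflex.trading import TransactionRecord

        txs = []
        for e in build_schedule(seed=3):
            alien = m.best_alien(e.mineral)  # always the old mapping
            mat = m if e.phase == "pre_reversal" else reverse_rules(m)
            txs.append(
                TransactionRecord(e.trial_index, e.mineral, alien,
                                  mat.reward(alien, e.mineral))
            )
        metrics = score_game(txs)
        assert metrics.learned_pre
        assert metrics.relearning_speed is None
        assert not metrics.learned_post

    def test_missing_trials_are_reported(self):
        txs = self._optimal_transactions()[:-2]
        with pytest.raises(ValueError, match=r"missing \[67, 68\]"):
            score_game(txs)

    def test_round_trip_through_csv(self, tmp_path):
        txs = self._optimal_transactions()
        df = pd.DataFrame(
            {
                "subject_id": "S001",
                "trial_index": [t.trial_index for t in txs],
                "mineral": [t.mineral for t in txs],
                "alien": [t.chosen_alien for t in txs],
                "reward": [t.reward for t in txs],
            }
        )
        path = tmp_path / "tx.csv"
        df.to_csv(path, index=False)
        back = transactions_from_frame(pd.read_csv(path))["S001"]
        assert score_game(back) == score_game(txs)


class TestMineral4Preference:
    def test_strong_preference_is_flagged(self):
        from metaflex.trading import TransactionRecord

        txs = [TransactionRecord(i + 1, 4, 2, 10) for i in range(17)]
        counts, flagged = mineral4_preference(txs)
        assert counts == (0, 17, 0)
        assert flagged

    def test_near_uniform_is_not_flagged(self):
        from metaflex.trading import TransactionRecord

        aliens = [1] * 6 + [2] * 6 + [3] * 5
        txs = [TransactionRecord(i + 1, 4, a, 10) for i, a in enumerate(aliens)]
        counts, flagged = mineral4_preference(txs)
        assert counts == (6, 6, 5)
        assert not flagged

    def test_counts_conserve_mineral4_trials(self, rng):
        matrix = build_reward_matrix()
        txs = random_transaction_sequence(rng, matrix, 68)
        counts, _ = mineral4_preference(txs)
        assert sum(counts) == sum(t.mineral == 4 for t in txs)
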