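"""From-scratch reproducibility checks for the package's core claims.

Every function here recomputes a checkable quantity by running the package
on freshly generated data: design constants of the two tasks, the worked
correlation statistics, recovery properties of the meta-d' engine, the
learning-detector equivalence against an independent exhaustive scan, and
the end-to-end power/calibration studies on synthetic cohorts.  The
acceptance script and the test suite both call these functions.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, SubjectParams, simulate_cohort, simulate_confidence_trials
from .hierarchical import HierarchicalMetaDModel
from .inference import (
    compare_correlations,
    fisher_z,
    partial_spearman,
    two_way_anova,
)
from .metad import MetaDModel, expected_type2_counts
from .pipeline import _apply_censoring, score_games
from .sdt import tabulate_type2, trials_from_frame
from .trading import (
    TransactionRecord,
    build_reward_matrix,
    build_schedule,
    detect_learning,
    reverse_rules,
)

_STUDY_N_PER_GROUP = 33


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


# ---- design constants ----------------------------------------------------


def design_constants(seed: int = 0) -> dict:
    """Trial-structure constants of the generated tasks."""
    schedule = build_schedule(seed)
    pre = [e for e in schedule if e.phase == "pre_reversal"]
    p = SubjectParams("S001", "TD", "A", 1.4, 0.4, 3.5, 0.6, 0.05, 3, seed=seed)
    trials = simulate_confidence_trials(p)
    return {
        "n_trading_trials": len(schedule),
        "n_pre_reversal_trials": len(pre),
        "n_rotation_trials": len(trials),
        "n_different_trials": sum(t.stimulus == "different" for t in trials),
    }


def printed_statistics() -> dict:
    """The worked correlation statistics, recomputed from their inputs."""
    n = _STUDY_N_PER_GROUP
    return {
        "fisher_z_0384": fisher_z(0.384),
        "fisher_z_m0583": fisher_z(-0.583),
        "z_observed_learning_corr": compare_correlations(0.384, n, 0.033, n).z_observed,
        "z_observed_partial_corr": compare_correlations(0.463, n, 0.36, n).z_observed,
    }


# ---- meta-d' engine ------------------------------------------------------


def random_model_table(rng: np.random.Generator, n_per_stimulus: int = 150):
    """A random type-2 count table sampled from the generative meta model."""
    d = rng.uniform(0.8, 2.2)
    meta_d = rng.uniform(0.3, 2.5)
    c = rng.uniform(-0.3, 0.3)
    p = SubjectParams(
        "tmp", "TD", "A", d, meta_d / d, float(rng.uniform(2.2, 3.2)),
        0.6, 0.05, 3, seed=int(rng.integers(2**31 - 1)),
    )
    trials = simulate_confidence_trials(
        p, n_trials=2 * n_per_stimulus, criterion=c, rng=rng
    )
    return tabulate_type2(trials)


def metad_grid_agreement(seed: int, n_tables: int = 20) -> float:
    """Max |optimizer - exhaustive grid| meta-d' over random tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        model = MetaDModel(random_model_table(rng))
        fit = model.fit()
        grid = model.fit_grid()  # meta-d' in [0, 5], step 0.01
        worst = max(worst, abs(fit.meta_d - grid.meta_d))
    return worst


def metad_self_consistency() -> float:
    """|fitted - generating| meta-d' on model-implied expected counts."""
    t2 = expected_type2_counts(
        d_prime=1.5, criterion=0.0, meta_d=1.5,
        criteria_above=[0.5, 1.0, 1.5], criteria_below=[-0.5, -1.0, -1.5],
        n_per_stimulus=500,
    )
    fit = MetaDModel(t2).fit()
    return abs(fit.meta_d - 1.5)


def metad_recovery(seed: int, n_trials: int = 1000, n_rep: int = 100) -> float:
    """Median |fitted - true| meta-d' across true meta-d' in {0.5, 1.0, 1.5}.

    Simulated at d' = 1.5 with mean confidence at the scale midpoint so
    all four rating bins stay populated — the neutral operating point for
    benchmarking the estimator itself.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for true_meta_d in (0.5, 1.0, 1.5):
        for _ in range(n_rep):
            p = SubjectParams(
                "tmp", "TD", "A", 1.5, true_meta_d / 1.5, 2.5, 0.6, 0.05, 3,
                seed=int(rng.integers(2**31 - 1)),
            )
            trials = simulate_confidence_trials(p, n_trials=n_trials, rng=rng)
            fit = MetaDModel(tabulate_type2(trials)).fit()
            errors.append(abs(fit.meta_d - true_meta_d))
    return float(np.median(errors))


# ---- learning detector ---------------------------------------------------


def reference_learning_scan(transactions, matrix, convention="completion"):
    """Independent exhaustive scan implementing the two-condition criterion.

    Enumerates every candidate three-in-a-row of 20-coin rewards over the
    20-eligible (non-mineral-4) trials and checks the no-later-double-5
    condition explicitly.  Used only as an oracle for ``detect_learning``.
    """
    txs = list(transactions)
    elig = [i for i, t in enumerate(txs) if t.mineral != 4]
    for a in range(len(elig) - 2):
        i1, i2, i3 = elig[a], elig[a + 1], elig[a + 2]
        if txs[i1].reward == 20 and txs[i2].reward == 20 and txs[i3].reward == 20:
            later = [j for j in elig if j > i3]
            drop = False
            for k in range(len(later) - 1):
                if txs[later[k]].reward == 5 and txs[later[k + 1]].reward == 5:
                    drop = True
                    break
            if not drop:
                return (i3 + 1) if convention == "completion" else (i1 + 1)
    return None


def random_transaction_sequence(
    rng: np.random.Generator, matrix, length: int
) -> list[TransactionRecord]:
    """Random but matrix-consistent transactions (choices uniform)."""
    out = []
    for i in range(length):
        mineral = int(rng.integers(1, 5))
        alien = int(rng.integers(1, 4))
        out.append(
            TransactionRecord(
                trial_index=i + 1,
                mineral=mineral,
                chosen_alien=alien,
                reward=matrix.reward(alien, mineral),
            )
        )
    return out


def detector_agreement(seed: int, n_sequences: int = 1000) -> float:
    """Fraction of random sequences where detector and oracle agree."""
    rng = np.random.default_rng(seed)
    matrix = build_reward_matrix()
    matrices = (matrix, reverse_rules(matrix))
    agree = 0
    for i in range(n_sequences):
        m = matrices[i % 2]
        length = int(rng.integers(10, 49))
        txs = random_transaction_sequence(rng, m, length)
        convention = "completion" if i % 4 < 2 else "run_start"
        if detect_learning(txs, m, convention=convention) == reference_learning_scan(
            txs, m, convention=convention
        ):
            agree += 1
    return agree / n_sequences


# ---- end-to-end cohort studies ------------------------------------------


def _cohort_measures(seed: int, **spec_kwargs):
    data = simulate_cohort(CohortSpec(seed=seed, **spec_kwargs))
    game = score_games(data.transactions)
    df = data.truth.merge(game, on="subject_id")
    df = _apply_censoring(df, "rank_cap")
    mean_conf = data.trials.groupby("subject_id")["confidence"].mean()
    df["meta_bias"] = df["subject_id"].map(mean_conf)
    return data, df


def group_mratio_detection(seed: int, n_reps: int = 20) -> dict:
    """Power study: ASD/TD cohorts at true M-ratios 0.6 vs 0.4.

    Each replication simulates the full study frame (33 + 33 subjects, 72
    confidence trials each), estimates per-subject M-ratio hierarchically
    (the low-trial-count estimator of choice) and runs the group x region
    ANOVA on the per-subject posterior means.  Returns the fraction of
    replications with a significant group effect, and the fraction where
    the effect is significant with the generating direction (ASD > TD).
    """
    detected = 0
    directional = 0
    for rep in range(n_reps):
        data, _ = _cohort_measures(_child_seed(seed, rep))
        by_subject = trials_from_frame(data.trials)
        truth = data.truth.set_index("subject_id")
        ids = sorted(by_subject)
        tables = [tabulate_type2(by_subject[i]) for i in ids]
        groups = [str(truth.loc[i, "group"]) for i in ids]
        model = HierarchicalMetaDModel(tables, subject_ids=ids, groups=groups)
        res = model.fit(seed=_child_seed(seed, 1000 + rep))
        post = {}
        for gp in res.groups.values():
            post.update(dict(zip(gp.subject_ids, gp.subject_mratios)))
        keep = [i for i in ids if i in post]
        table = two_way_anova(
            [post[i] for i in keep],
            [str(truth.loc[i, "group"]) for i in keep],
            [str(truth.loc[i, "region"]) for i in keep],
        )
        p = float(table.loc[table["effect"] == "group", "p"].iloc[0])
        sig = p < 0.05
        detected += sig
        asd_higher = res.groups["ASD"].m_ratio_mean > res.groups["TD"].m_ratio_mean
        directional += sig and asd_higher
    return {
        "detection_rate": detected / n_reps,
        "directional_detection_rate": directional / n_reps,
    }


def bias_flexibility_detection(seed: int, n_reps: int = 20) -> dict:
    """Power study for the overconfidence-inflexibility association.

    Cohorts are generated at a bias/re-learning rank correlation of -0.5;
    each replication runs the partial Spearman between measured mean
    confidence and re-learning speed, controlling for learning speed.
    """
    detected = 0
    rhos = []
    for rep in range(n_reps):
        _, df = _cohort_measures(_child_seed(seed, 5000 + rep))
        res = partial_spearman(
            df["meta_bias"], df["relearning_speed"], df["learning_speed"]
        )
        rhos.append(res.rho)
        detected += (res.rho < 0) and (res.p < 0.05)
    return {
        "detection_rate": detected / n_reps,
        "median_partial_rho": float(np.median(rhos)),
    }


def anova_null_false_positive_rates(seed: int, n_reps: int = 500) -> dict:
    """Type-I error of the group x region ANOVA on no-effect cohorts.

    Subject-level measures are drawn with no group or region effect on the
    study layout (33 + 33 subjects, 18/15 region split); each effect's
    false-positive rate at alpha = .05 should sit at its nominal level.
    """
    rng = np.random.default_rng(seed)
    groups = ["ASD"] * 33 + ["TD"] * 33
    regions = (["A"] * 18 + ["B"] * 15) * 2
    hits = {"group": 0, "region": 0, "group:region": 0}
    for _ in range(n_reps):
        y = rng.normal(size=66)
        table = two_way_anova(y, groups, regions)
        for effect in hits:
            p = float(table.loc[table["effect"] == effect, "p"].iloc[0])
            hits[effect] += p < 0.05
    return {k: v / n_reps for k, v in hits.items()}
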