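"""End-to-end orchestration: data in, fits and statistics out.

``run_pipeline`` ties the stages together: ingest (or simulate) the
confidence-rated mental-rotation trials and the trading-game transactions,
fit per-subject type-1/type-2 SDT measures, score learning and re-learning
speeds, then run the group-level inference battery and write a reproducible
report bundle (per-subject fits, game metrics, statistics table, log).

Censored speeds (subjects who never met the learning criterion) enter rank
correlations either capped at the worst rank (default: phase length + 1,
which ranks them behind every learner) or are excluded, per configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .inference import (
    compare_correlations,
    mixed_anova,
    partial_spearman,
    spearman,
    two_way_anova,
)
from .metad import MetaDModel
from .sdt import STIMULI, compute_meta_bias, tabulate_type2, trials_from_frame
from .trading import (
    N_POST,
    N_PRE,
    N_TRIALS,
    REWARDS,
    build_reward_matrix,
    metrics_to_frame,
    score_game,
    transactions_from_frame,
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run byte for byte."""

    out_dir: str = "metaflex_out"
    seed: int = 0
    input_trials: str | None = None
    input_transactions: str | None = None
    simulate: bool = True
    n_sim_subjects_per_cell: tuple[int, int] | int | None = None
    n_levels: int = 4
    learning_convention: str = "completion"
    censoring: str = "rank_cap"  # or "exclude"
    hierarchical: bool = False
    correlation_bias_flexibility: float = -0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SchemaReport:
    path: str
    kind: str
    passed: bool
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def validate_input(path: str, kind: str) -> SchemaReport:
    """Validate a trials or transactions CSV; diagnostics carry row numbers."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file
        raise ValueError(f"cannot read {path}: {exc}") from exc
    errors: list[str] = []
    warns: list[str] = []
    if kind == "trials":
        required = {"subject_id", "group", "region", "trial_index", "stimulus",
                    "response", "confidence"}
        expected_n = 72
    elif kind == "transactions":
        required = {"subject_id", "trial_index", "mineral", "alien", "reward"}
        expected_n = N_TRIALS
    else:
        raise ValueError(f"unknown kind {kind!r}")
    missing = required - set(df.columns)
    if missing:
        errors.append(f"missing columns: {sorted(missing)}")
        return SchemaReport(str(path), kind, False, errors, warns)

    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        if kind == "trials":
            if row.stimulus not in STIMULI:
                errors.append(f"row {i}: stimulus {row.stimulus!r} invalid")
            if row.response not in STIMULI:
                errors.append(f"row {i}: response {row.response!r} invalid")
            if not 1 <= int(row.confidence) <= 4:
                errors.append(f"row {i}: confidence {row.confidence} outside 1..4")
        else:
            if int(row.reward) not in REWARDS:
                errors.append(f"row {i}: reward {row.reward} not in {REWARDS}")
            if not 1 <= int(row.alien) <= 3:
                errors.append(f"row {i}: alien {row.alien} outside 1..3")
            if not 1 <= int(row.mineral) <= 4:
                errors.append(f"row {i}: mineral {row.mineral} outside 1..4")
        if len(errors) >= 50:
            errors.append("... further errors suppressed")
            break

    for sid, n in df.groupby("subject_id").size().items():
        if n != expected_n:
            warns.append(f"subject {sid}: {n} rows, expected {expected_n}")
    return SchemaReport(str(path), kind, not errors, errors, warns)


# ---- per-subject stages --------------------------------------------------


def fit_metacognition(trials_df: pd.DataFrame, n_levels: int = 4) -> pd.DataFrame:
    """Per-subject SDT fits: d', c, meta-d', M-ratio, bias, accuracy-split confidence."""
    by_subject = trials_from_frame(trials_df)
    meta = trials_df.drop_duplicates("subject_id").set_index("subject_id")
    rows = []
    for sid, trials in by_subject.items():
        res = MetaDModel.from_trials(trials, n_levels=n_levels).fit()
        conf_correct = [t.confidence for t in trials if t.correct]
        conf_incorrect = [t.confidence for t in trials if not t.correct]
        rows.append(
            {
                "subject_id": sid,
                "group": meta.loc[sid, "group"] if "group" in meta else "all",
                "region": meta.loc[sid, "region"] if "region" in meta else "all",
                "d_prime": res.d_prime,
                "criterion": res.criterion,
                "meta_d": res.meta_d,
                "m_ratio": res.m_ratio,
                "meta_bias": compute_meta_bias(trials),
                "conf_correct": float(np.mean(conf_correct)) if conf_correct else np.nan,
                "conf_incorrect": float(np.mean(conf_incorrect)) if conf_incorrect else np.nan,
                "n_correct": len(conf_correct),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)


def score_games(transactions_df: pd.DataFrame, convention: str = "completion") -> pd.DataFrame:
    """Per-subject learning and re-learning speeds from the transactions table."""
    matrix = build_reward_matrix()
    by_subject = transactions_from_frame(transactions_df)
    metrics = {
        sid: score_game(txs, matrix, convention=convention)
        for sid, txs in by_subject.items()
    }
    return metrics_to_frame(metrics).sort_values("subject_id").reset_index(drop=True)


def _apply_censoring(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Resolve censored speeds for correlation analyses.

    ``rank_cap`` assigns censored subjects one trial beyond the phase
    length (worst rank); ``exclude`` drops them.
    """
    out = df.copy()
    if policy == "rank_cap":
        out["learning_speed"] = out["learning_speed"].fillna(N_PRE + 1)
        out["relearning_speed"] = out["relearning_speed"].fillna(N_POST + 1)
    elif policy == "exclude":
        out = out.dropna(subset=["learning_speed", "relearning_speed"])
    else:
        raise ValueError(f"unknown censoring policy {policy!r}")
    return out


# ---- the statistics battery ---------------------------------------------


def _corr_rows(analysis: str, label: str, res) -> dict:
    return {
        "analysis": analysis,
        "effect": label,
        "statistic": "rho",
        "value": res.rho,
        "df1": np.nan,
        "df2": res.n,
        "p": res.p,
        "effect_size": res.z,
    }


def analysis_battery(cohort: pd.DataFrame) -> pd.DataFrame:
    """The full inference layer on an assembled subject-level table.

    ``cohort`` needs columns: group, region, d_prime, m_ratio, meta_bias,
    conf_correct, conf_incorrect, learning_speed, relearning_speed (already
    censor-resolved).  Returns a long-format results table.
    """
    rows: list[dict] = []

    def add_anova(analysis: str, table: pd.DataFrame) -> None:
        for r in table.itertuples(index=False):
            rows.append(
                {
                    "analysis": analysis,
                    "effect": r.effect,
                    "statistic": "F",
                    "value": r.F,
                    "df1": r.df_effect,
                    "df2": r.df_error,
                    "p": r.p,
                    "effect_size": r.partial_eta_sq,
                }
            )

    g, r_ = cohort["group"], cohort["region"]
    add_anova("anova_d_prime", two_way_anova(cohort["d_prime"], g, r_))
    add_anova("mixed_anova_confidence", mixed_anova(cohort))
    add_anova("anova_m_ratio", two_way_anova(cohort["m_ratio"], g, r_))
    add_anova(
        "ancova_relearning",
        two_way_anova(
            cohort["relearning_speed"], g, r_, covariate=cohort["learning_speed"]
        ),
    )

    rows.append(
        _corr_rows(
            "spearman", "learning~relearning (all)",
            spearman(cohort["learning_speed"], cohort["relearning_speed"]),
        )
    )
    per_group: dict[str, dict[str, object]] = {}
    for grp, sub in cohort.groupby("group"):
        res_mr_rel = spearman(sub["m_ratio"], sub["relearning_speed"])
        res_mr_learn = spearman(sub["m_ratio"], sub["learning_speed"])
        res_bias_learn = spearman(sub["meta_bias"], sub["learning_speed"])
        res_bias_rel = spearman(sub["meta_bias"], sub["relearning_speed"])
        res_partial = partial_spearman(
            sub["meta_bias"], sub["relearning_speed"], sub["learning_speed"]
        )
        per_group[grp] = {
            "m_ratio~learning": res_mr_learn,
            "bias~relearning|learning": res_partial,
        }
        rows.append(_corr_rows("spearman", f"m_ratio~relearning ({grp})", res_mr_rel))
        rows.append(_corr_rows("spearman", f"m_ratio~learning ({grp})", res_mr_learn))
        rows.append(_corr_rows("spearman", f"bias~learning ({grp})", res_bias_learn))
        rows.append(_corr_rows("spearman", f"bias~relearning ({grp})", res_bias_rel))
        rows.append(
            _corr_rows("partial_spearman", f"bias~relearning|learning ({grp})", res_partial)
        )
    pooled_partial = partial_spearman(
        cohort["meta_bias"], cohort["relearning_speed"], cohort["learning_speed"]
    )
    rows.append(
        _corr_rows("partial_spearman", "bias~relearning|learning (all)", pooled_partial)
    )

    if len(per_group) == 2:
        (g1, d1), (g2, d2) = sorted(per_group.items())
        for label in ("m_ratio~learning", "bias~relearning|learning"):
            r1, r2 = d1[label], d2[label]
            cmp_ = compare_correlations(r1.rho, r1.n, r2.rho, r2.n)
            rows.append(
                {
                    "analysis": "compare_correlations",
                    "effect": f"{label} ({g1} vs {g2})",
                    "statistic": "z_observed",
                    "value": cmp_.z_observed,
                    "df1": r1.n,
                    "df2": r2.n,
                    "p": cmp_.p,
                    "effect_size": np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---- orchestration -------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle.

    Returns a dict with the in-memory tables (``fits``, ``game_metrics``,
    ``stats``) and the output paths.  Identical config and seed produce
    byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"metaflex {__version__}", f"seed {config.seed}"]

    if config.simulate:
        spec_kwargs = {
            "seed": config.seed,
            "correlation_bias_flexibility": config.correlation_bias_flexibility,
            "n_levels": config.n_levels,
        }
        if config.n_sim_subjects_per_cell is not None:
            spec_kwargs["n_per_cell"] = config.n_sim_subjects_per_cell
        spec = CohortSpec(**spec_kwargs)
        data = simulate_cohort(spec)
        trials_df, tx_df = data.trials, data.transactions
        _write_csv(trials_df, out / "trials.csv")
        _write_csv(tx_df, out / "transactions.csv")
        _write_csv(data.truth, out / "truth.csv")
        _write_csv(data.schedule, out / "schedule.csv")
        log.append(f"simulated cohort: {len(data.params)} subjects")
    else:
        if not config.input_trials or not config.input_transactions:
            raise ValueError("need input_trials and input_transactions unless simulating")
        for path, kind in (
            (config.input_trials, "trials"),
            (config.input_transactions, "transactions"),
        ):
            report = validate_input(path, kind)
            for w in report.warnings:
                warnings.warn(f"{path}: {w}")
            if not report.passed:
                raise ValueError(
                    f"{path} failed schema validation: " + "; ".join(report.errors)
                )
        trials_df = pd.read_csv(config.input_trials)
        tx_df = pd.read_csv(config.input_transactions)
        log.append(f"loaded {config.input_trials}, {config.input_transactions}")

    fits = fit_metacognition(trials_df, n_levels=config.n_levels)
    game = score_games(tx_df, convention=config.learning_convention)

    if config.hierarchical:
        from .hierarchical import HierarchicalMetaDModel

        by_subject = trials_from_frame(trials_df)
        ids = sorted(by_subject)
        meta = fits.set_index("subject_id")
        tables = [tabulate_type2(by_subject[i], n_levels=config.n_levels) for i in ids]
        hmodel = HierarchicalMetaDModel(
            tables, subject_ids=ids, groups=[str(meta.loc[i, "group"]) for i in ids]
        )
        hres = hmodel.fit(seed=config.seed + 1)
        post_means = {}
        for gp in hres.groups.values():
            post_means.update(dict(zip(gp.subject_ids, gp.subject_mratios)))
        fits["m_ratio_mle"] = fits["m_ratio"]
        fits["m_ratio"] = fits["subject_id"].map(post_means)
        (out / "hierarchical_report.json").write_text(
            json.dumps(
                {
                    "summary": hres.summary(),
                    "groups": {
                        name: {
                            "log_mratio_mean": gp.log_mratio_mean,
                            "log_mratio_sd": gp.log_mratio_sd,
                            "log_mratio_ci": list(gp.log_mratio_ci),
                            "m_ratio_mean": gp.m_ratio_mean,
                            "rhat": gp.rhat,
                            "ess": gp.ess,
                            "converged": gp.converged,
                        }
                        for name, gp in hres.groups.items()
                    },
                    "contrast": hres.contrast,
                    "seed": hres.seed,
                },
                indent=2,
            )
            + "\n"
        )
        log.append("hierarchical fit: " + hres.summary().replace("\n", " | "))

    cohort = fits.merge(game, on="subject_id", how="inner").dropna(subset=["m_ratio"])
    cohort = _apply_censoring(cohort, config.censoring)
    stats = analysis_battery(cohort)

    _write_csv(fits, out / "fits.csv")
    _write_csv(game, out / "game_metrics.csv")
    _write_csv(stats, out / "stats_report.csv")

    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True)
    log.append("config " + cfg_json)
    log.append("config_hash " + hashlib.sha256(cfg_json.encode()).hexdigest()[:16])
    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "config.json").write_text(cfg_json + "\n")

    return {
        "fits": fits,
        "game_metrics": game,
        "stats": stats,
        "out_dir": out,
    }
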