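"""Group-level inference: factorial and split-plot ANOVA, rank correlations.

Implements the statistical layer applied to the subject-level measures:

* two-way (group x region) ANOVA with Type-III sums of squares and partial
  eta squared, optionally with a covariate (AN(C)OVA);
* a split-plot (mixed repeated-measures) ANOVA for a two-level
  within-subject factor, computed exactly through its classical
  decomposition: between effects from subject means, within effects from
  difference scores;
* Spearman and first-order partial Spearman correlations (Pearson on
  average ranks), with Fisher's variance-stabilising z transform and the
  two-sample Z test for comparing independent correlations;
* the sensitivity power calculation for a factorial design: the minimal
  Cohen's f detectable at given alpha and power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.stats import f as f_dist
from scipy.stats import ncf, norm, rankdata
from statsmodels.formula.api import ols

__all__ = [
    "AnovaResult",
    "CorrResult",
    "CorrComparison",
    "two_way_anova",
    "mixed_anova",
    "spearman",
    "partial_spearman",
    "fisher_z",
    "compare_correlations",
    "anova_sensitivity",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class CorrResult:
    rho: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class CorrComparison:
    z_observed: float
    p: float  # one-sided


def _results_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _effects_from_ols(
    data: pd.DataFrame,
    formula: str,
    rename: dict[str, str],
    drop: tuple[str, ...] = ("Intercept",),
) -> list[AnovaResult]:
    """Type-III effect tests by drop-one-term model comparison.

    With sum-coded factors, removing a term from the full model and
    comparing residual sums of squares reproduces Type-III sums of squares
    (the marginal test of each effect adjusted for all others, including
    interactions).
    """
    import statsmodels.api as sm

    with warnings.catch_warnings():
        # degenerate (zero-variance) data trip rank warnings inside
        # statsmodels; the 0/0 case is resolved explicitly below
        warnings.simplefilter("ignore")
        full = ols(formula, data=data).fit()
        ss_err = float(full.ssr)
        df_err = int(full.df_resid)
        design_info = full.model.data.design_info
        X = np.asarray(full.model.exog)
        y = np.asarray(full.model.endog)
        out = []
        for term in design_info.term_names:
            if term in drop:
                continue
            sl = design_info.term_name_slices[term]
            keep_cols = [i for i in range(X.shape[1]) if not sl.start <= i < sl.stop]
            if keep_cols:
                reduced_ssr = float(sm.OLS(y, X[:, keep_cols]).fit().ssr)
            else:
                reduced_ssr = float(np.sum(y**2))  # empty model: SSR about 0
            ss = max(reduced_ssr - ss_err, 0.0)
            dfe = sl.stop - sl.start
            if ss < 1e-12 and ss_err < 1e-12:
                ss, F, p = 0.0, 0.0, 1.0  # no variance anywhere
            elif ss_err < 1e-12:
                F, p = np.inf, 0.0
            else:
                F = (ss / dfe) / (ss_err / df_err)
                p = float(f_dist.sf(F, dfe, df_err))
            pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            out.append(
                AnovaResult(
                    effect=rename.get(str(term), str(term)),
                    F=float(F),
                    df_effect=dfe,
                    df_error=df_err,
                    p=p,
                    partial_eta_sq=float(pes),
                )
            )
    return out


def two_way_anova(
    values,
    factor_group,
    factor_region,
    covariate=None,
    factor_names: tuple[str, str] = ("group", "region"),
) -> pd.DataFrame:
    """Two-factor ANOVA with Type-III SS and partial eta squared.

    Returns one row per effect (main effects, interaction and, when given,
    the covariate) with columns ``effect, F, df_effect, df_error, p,
    partial_eta_sq``.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "A": np.asarray(factor_group),
            "B": np.asarray(factor_region),
        }
    ).dropna(subset=["y"])
    cells = df.groupby(["A", "B"]).size()
    n_a, n_b = df["A"].nunique(), df["B"].nunique()
    if n_a < 2 or n_b < 2 or len(cells) < n_a * n_b or (cells < 1).any():
        raise ValueError(
            "every factor needs >= 2 levels and every cell >= 1 observation"
        )
    a_name, b_name = factor_names
    rename = {
        "C(A, Sum)": a_name,
        "C(B, Sum)": b_name,
        "C(A, Sum):C(B, Sum)": f"{a_name}:{b_name}",
        "x": "covariate",
    }
    formula = "y ~ C(A, Sum) * C(B, Sum)"
    if covariate is not None:
        df["x"] = np.asarray(covariate, dtype=float)
        formula += " + x"
    return _results_frame(_effects_from_ols(df, formula, rename))


def mixed_anova(
    data: pd.DataFrame,
    within_cols: tuple[str, str] = ("conf_correct", "conf_incorrect"),
    between_cols: tuple[str, str] = ("group", "region"),
    within_name: str = "accuracy",
) -> pd.DataFrame:
    """Split-plot ANOVA: one two-level within factor, two between factors.

    ``data`` holds one row per subject with both within-level means (for
    the confidence analysis: mean confidence on correct and on incorrect
    responses).  Subjects missing a within level are excluded with a
    warning — a subject with no errors has no "incorrect" mean.

    With exactly two within levels the classical split-plot decomposition
    is exact: between-subject effects are a factorial ANOVA on the subject
    means; the within main effect and its interactions are the Type-III
    test of the intercept and factor terms in a model of the difference
    scores.
    """
    c1, c2 = within_cols
    factors = list(dict.fromkeys(between_cols))  # unique, order kept
    complete = data.dropna(subset=[c1, c2]).copy()
    dropped = len(data) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} subject(s) missing a within-subject level were excluded"
        )
    complete["A"] = complete[factors[0]]
    g = factors[0]
    if len(factors) == 2:
        complete["B"] = complete[factors[1]]
        r = factors[1]
        rhs = "C(A, Sum) * C(B, Sum)"
        rename_between = {
            "C(A, Sum)": g,
            "C(B, Sum)": r,
            "C(A, Sum):C(B, Sum)": f"{g}:{r}",
        }
        rename_within = {
            "Intercept": within_name,
            "C(A, Sum)": f"{within_name}:{g}",
            "C(B, Sum)": f"{within_name}:{r}",
            "C(A, Sum):C(B, Sum)": f"{within_name}:{g}:{r}",
        }
    else:
        rhs = "C(A, Sum)"
        rename_between = {"C(A, Sum)": g}
        rename_within = {"Intercept": within_name, "C(A, Sum)": f"{within_name}:{g}"}
    complete["m"] = (complete[c1] + complete[c2]) / 2.0
    complete["d"] = complete[c1] - complete[c2]

    between = _effects_from_ols(
        complete.rename(columns={"m": "y"}), f"y ~ {rhs}", rename_between
    )
    within = _effects_from_ols(
        complete.rename(columns={"d": "y"}), f"y ~ {rhs}", rename_within, drop=()
    )
    return _results_frame(within + between)


def _check_rank_variance(x: np.ndarray, name: str) -> np.ndarray:
    ranks = rankdata(x)
    if np.ptp(ranks) == 0:
        raise ValueError(f"zero rank variance in {name}")
    return ranks


def spearman(
    x,
    y,
    method: str = "t",
    n_resamples: int = 9999,
    seed: int | None = None,
) -> CorrResult:
    """Spearman rank correlation with Fisher z.

    ``method="t"`` (default) uses the t approximation for the p-value,
    appropriate at the cohort sizes involved; ``method="permutation"``
    computes an exact-style permutation p-value instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    _check_rank_variance(x, "x")
    _check_rank_variance(y, "y")
    rho, p = stats.spearmanr(x, y)
    if method == "permutation":
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=n_resamples,
            rng=np.random.default_rng(seed),
        )
        p = float(res.pvalue)
    z = float(np.arctanh(rho)) if abs(rho) < 1 else float(np.sign(rho) * np.inf)
    return CorrResult(rho=float(rho), z=z, p=float(p), n=int(x.size))


def partial_spearman(x, y, covariate) -> CorrResult:
    """First-order partial Spearman: Pearson partial correlation on ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = x.size
    if not (y.size == n and c.size == n) or n < 5:
        raise ValueError("need three aligned samples with n >= 5")
    rx = _check_rank_variance(x, "x")
    ry = _check_rank_variance(y, "y")
    rc = _check_rank_variance(c, "covariate")
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xc = np.corrcoef(rx, rc)[0, 1]
    r_yc = np.corrcoef(ry, rc)[0, 1]
    if abs(r_xc) >= 1.0 - 1e-12 or abs(r_yc) >= 1.0 - 1e-12:
        raise ValueError("degenerate control: covariate collinear with an input")
    rho = (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc**2) * (1 - r_yc**2))
    df = n - 3
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = 2 * stats.t.sf(abs(t), df)
    z = float(np.arctanh(rho_c))
    return CorrResult(rho=float(rho), z=z, p=float(p), n=int(n))


def fisher_z(rho: float) -> float:
    """Variance-stabilising transform z = atanh(rho)."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return float(np.arctanh(rho))


def compare_correlations(rho1: float, n1: int, rho2: float, n2: int) -> CorrComparison:
    """Two-sample Z test for independent correlations (one-sided p).

    Z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (fisher_z(rho1) - fisher_z(rho2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return CorrComparison(z_observed=float(z), p=float(norm.sf(abs(z))))


def anova_power(
    f: float, n_total: int, df_effect: int, n_cells: int, alpha: float = 0.05
) -> float:
    """Power of a factorial-effect F test at Cohen's effect size ``f``."""
    df_error = n_total - n_cells
    if df_error <= 0:
        raise ValueError("n_total must exceed the number of cells")
    lam = f * f * n_total
    f_crit = f_dist.ppf(1 - alpha, df_effect, df_error)
    power = 1.0 - ncf.cdf(f_crit, df_effect, df_error, lam)
    if not np.isfinite(power):  # ncf.cdf underflows at very large lambda
        return 1.0
    return float(power)


def anova_sensitivity(
    n_total: int,
    alpha: float = 0.05,
    power: float = 0.80,
    df_effect: int = 1,
    n_cells: int = 4,
) -> float:
    """Minimal detectable Cohen's f for a factorial effect.

    The smallest f whose noncentral-F power at (df_effect,
    n_total - n_cells) error degrees of freedom reaches the target.
    """
    if not (0.0 < power < 1.0):
        raise ValueError("power must lie in (0, 1)")
    lo, hi = 1e-6, 1.0
    while anova_power(hi, n_total, df_effect, n_cells, alpha) < power:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError("target power unattainable at this sample size")
    return float(
        brentq(
            lambda f: anova_power(f, n_total, df_effect, n_cells, alpha) - power,
            lo,
            hi,
            xtol=1e-6,
        )
    )
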