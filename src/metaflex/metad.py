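"""Maximum-likelihood meta-d' estimation (type-2 SDT).

The meta-d' model asks: what type-1 sensitivity would an ideal observer
need so that its confidence ratings discriminate correct from incorrect
responses exactly as well as the observed ratings do?  Fitting works on the
response-conditional confidence counts:

* meta-level evidence is unit-variance Gaussian with means +/- meta_d / 2
  for the two stimulus classes;
* the type-1 criterion c is carried over to the meta level scaled by
  meta_d / d', so the meta model is anchored to the observed response bias;
* on each side of the scaled criterion, ``n_levels - 1`` type-2 criteria
  partition the evidence axis into confidence bins; bin probabilities are
  normal-CDF differences renormalised within each (stimulus, response)
  cell;
* the likelihood is the product of the resulting multinomials over the
  four (stimulus, response) cells, with a 1e-10 floor on bin probabilities
  (no count padding).

Metacognitive efficiency is the M-ratio meta_d / d', which discounts
metacognitive sensitivity for task performance so that subjects and groups
of different ability can be compared.

``MetaDModel.fit`` runs a bounded quasi-Newton search from several
deterministic starting points; ``MetaDModel.fit_grid`` is an exhaustive
profile-likelihood scan over meta_d used for cross-checking the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .sdt import (
    Type2Counts,
    TrialRecord,
    compute_type1_sdt,
    tabulate_type1,
    tabulate_type2,
)

PROB_FLOOR = 1e-10
_INCR_BOUNDS = (-4.6, 2.5)  # log-space criterion increments, ~0.01 .. 12


def _type1_from_table(counts: Type2Counts) -> tuple[float, float]:
    """Type-1 d'/c from the (possibly non-integer) collapsed marginals."""
    c1 = counts.counts.sum(axis=2)  # (stimulus, response)
    n_noise, n_signal = c1[0].sum(), c1[1].sum()
    if n_noise <= 0 or n_signal <= 0:
        raise ValueError("both stimulus classes must be present")

    def adjust(k: float, n: float) -> float:
        rate = k / n
        return min(max(rate, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    zh = norm.ppf(adjust(c1[1, 1], n_signal))
    zf = norm.ppf(adjust(c1[0, 1], n_noise))
    return float(zh - zf), float(-0.5 * (zh + zf))


def _criteria_from_increments(c_meta: float, log_incr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monotone type-2 criteria on both sides of the scaled criterion.

    The first half of ``log_incr`` places criteria above ``c_meta``
    (ascending), the second half below (descending); exponentiating the
    increments enforces strict ordering.
    """
    k = log_incr.size // 2
    above = c_meta + np.cumsum(np.exp(log_incr[:k]))
    below = c_meta - np.cumsum(np.exp(log_incr[k:]))
    return above, below


def response_conditional_probs(
    meta_d: float,
    c_meta: float,
    criteria_above: np.ndarray,
    criteria_below: np.ndarray,
) -> np.ndarray:
    """P(confidence = j | stimulus s, response r) under the meta model.

    Returns an array of shape (2, 2, n_levels) on the axis convention of
    :class:`~metaflex.sdt.Type2Counts` (stimulus 0 = "different",
    1 = "identical"; same for response).
    """
    n_levels = criteria_above.size + 1
    mu = np.array([-meta_d / 2.0, meta_d / 2.0])

    # response "identical": evidence region (c_meta, inf); edges ascending.
    # response "different": region (-inf, c_meta); conf 1 nearest c_meta.
    hi_edges = np.concatenate(([c_meta], criteria_above, [np.inf]))
    lo_edges = np.concatenate(([c_meta], criteria_below, [-np.inf]))

    cdf_hi = ndtr(hi_edges[None, :] - mu[:, None])
    cdf_lo = ndtr(lo_edges[None, :] - mu[:, None])
    cdf_c = ndtr(c_meta - mu)
    denom_hi = np.maximum(1.0 - cdf_c, PROB_FLOOR)
    denom_lo = np.maximum(cdf_c, PROB_FLOOR)

    probs = np.empty((2, 2, n_levels))
    probs[:, 1, :] = np.diff(cdf_hi, axis=1) / denom_hi[:, None]
    probs[:, 0, :] = -np.diff(cdf_lo, axis=1) / denom_lo[:, None]
    return probs


def expected_type2_counts(
    d_prime: float,
    criterion: float,
    meta_d: float,
    criteria_above: Sequence[float],
    criteria_below: Sequence[float],
    n_per_stimulus: float,
) -> Type2Counts:
    """Model-implied expected counts (may be non-integer).

    Type-1 response probabilities come from the type-1 model (d', c);
    confidence bins from the meta model.  Useful for self-consistency
    checks: fitting the expected counts should recover ``meta_d``.
    """
    criteria_above = np.asarray(criteria_above, dtype=float)
    criteria_below = np.asarray(criteria_below, dtype=float)
    n_levels = criteria_above.size + 1
    mu1 = np.array([-d_prime / 2.0, d_prime / 2.0])
    c_meta = criterion * (meta_d / d_prime) if d_prime != 0 else criterion
    p_conf = response_conditional_probs(meta_d, c_meta, criteria_above, criteria_below)
    counts = np.empty((2, 2, n_levels))
    for s in (0, 1):
        p_ident = 1.0 - norm.cdf(criterion - mu1[s])
        counts[s, 1] = n_per_stimulus * p_ident * p_conf[s, 1]
        counts[s, 0] = n_per_stimulus * (1.0 - p_ident) * p_conf[s, 0]
    return Type2Counts(counts, n_levels=n_levels)


@dataclass
class MetaDResults:
    """Fitted meta-d' model for one subject."""

    meta_d: float
    m_ratio: float
    d_prime: float
    criterion: float
    criteria_above: np.ndarray
    criteria_below: np.ndarray
    llf: float
    converged: bool
    message: str
    n_trials: float
    n_levels: int

    @property
    def type2_criteria(self) -> np.ndarray:
        """All 2(n_levels-1) absolute type-2 criteria, ascending."""
        return np.concatenate((self.criteria_below[::-1], self.criteria_above))

    def summary(self) -> str:
        lines = [
            "Meta-d' model (response-conditional multinomial MLE)",
            "-" * 52,
            f"n trials          {self.n_trials:10.0f}",
            f"d'                {self.d_prime:10.4f}",
            f"criterion c       {self.criterion:10.4f}",
            f"meta-d'           {self.meta_d:10.4f}",
            f"M-ratio           {self.m_ratio:10.4f}",
            f"log-likelihood    {self.llf:10.4f}",
            f"converged         {str(self.converged):>10}",
        ]
        crit = ", ".join(f"{c:.3f}" for c in self.type2_criteria)
        lines.append(f"type-2 criteria   [{crit}]")
        return "\n".join(lines)


class MetaDModel:
    """Meta-d' model for one subject's type-2 count table.

    Parameters
    ----------
    counts
        Stimulus x response x confidence table.
    d_prime, criterion
        Type-1 parameters.  By default they are computed from the collapsed
        type-1 table with the 1/(2N) extreme-rate correction.
    """

    def __init__(
        self,
        counts: Type2Counts,
        d_prime: float | None = None,
        criterion: float | None = None,
    ):
        self.counts = counts
        self.n_levels = counts.n_levels
        if d_prime is None or criterion is None:
            d_prime, criterion = _type1_from_table(counts)
        self.d_prime = float(d_prime)
        self.criterion = float(criterion)

    @classmethod
    def from_trials(cls, trials: Iterable[TrialRecord], n_levels: int = 4) -> "MetaDModel":
        trials = list(trials)
        t1 = tabulate_type1(trials)
        d, c = compute_type1_sdt(t1)
        return cls(tabulate_type2(trials, n_levels=n_levels), d_prime=d, criterion=c)

    # ---- likelihood ------------------------------------------------------

    def _c_meta(self, meta_d: float) -> float:
        if self.d_prime == 0 or not np.isfinite(meta_d):
            return self.criterion
        return self.criterion * (meta_d / self.d_prime)

    def loglike(self, meta_d: float, log_incr: np.ndarray) -> float:
        c_meta = self._c_meta(meta_d)
        above, below = _criteria_from_increments(c_meta, np.asarray(log_incr))
        probs = response_conditional_probs(meta_d, c_meta, above, below)
        return float(np.sum(self.counts.counts * np.log(np.maximum(probs, PROB_FLOOR))))

    def _neg_ll(self, x: np.ndarray) -> float:
        return -self.loglike(x[0], x[1:])

    def _default_increments(self) -> np.ndarray:
        # thresholds ~0.5 apart on either side of the scaled criterion
        return np.full(2 * (self.n_levels - 1), np.log(0.5))

    def _make_results(self, meta_d, log_incr, llf, converged, message) -> MetaDResults:
        c_meta = self._c_meta(meta_d)
        above, below = _criteria_from_increments(c_meta, log_incr)
        m_ratio = meta_d / self.d_prime if self.d_prime != 0 else np.nan
        return MetaDResults(
            meta_d=float(meta_d),
            m_ratio=float(m_ratio),
            d_prime=self.d_prime,
            criterion=self.criterion,
            criteria_above=above,
            criteria_below=below,
            llf=float(llf),
            converged=bool(converged),
            message=str(message),
            n_trials=self.counts.n_total,
            n_levels=self.n_levels,
        )

    # ---- fitting ---------------------------------------------------------

    def fit(self, n_starts: int = 5, tol: float = 1e-8) -> MetaDResults:
        """Bounded quasi-Newton MLE from deterministic starting points."""
        if abs(self.d_prime) < 1e-8:
            res = self._make_results(
                np.nan, self._default_increments(), np.nan, False,
                "d' = 0: M-ratio undefined",
            )
            return res
        d = abs(self.d_prime)
        start_metad = np.array([0.1, 0.5 * d, d, 1.5 * d, -0.5 * d])[:n_starts]
        incr0 = self._default_increments()
        bounds = [(-5.0, 8.0)] + [_INCR_BOUNDS] * incr0.size
        best = None
        for m0 in start_metad:
            x0 = np.concatenate(([m0], incr0))
            res = minimize(
                self._neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        return self._make_results(
            best.x[0], best.x[1:], -best.fun, best.success, best.message
        )

    def profile_loglike(
        self, meta_d_grid: np.ndarray, tol: float = 1e-8
    ) -> np.ndarray:
        """Profile log-likelihood over meta_d (criteria optimised out).

        The criterion optimisation is warm-started from the previous grid
        point, so a dense grid is cheap.
        """
        if abs(self.d_prime) < 1e-8:
            raise ValueError("d' = 0: meta-d' profile undefined")
        grid = np.asarray(meta_d_grid, dtype=float)
        out = np.empty(grid.size)
        incr = self._default_increments()
        bounds = [_INCR_BOUNDS] * incr.size
        for i, m in enumerate(grid):
            res = minimize(
                lambda z, m=m: -self.loglike(m, z),
                incr, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "maxiter": 300},
            )
            out[i] = -res.fun
            incr = res.x
        return out

    def fit_grid(
        self, grid: np.ndarray | None = None, tol: float = 1e-8
    ) -> MetaDResults:
        """Exhaustive profile scan over meta_d (default [0, 5] step 0.01)."""
        if grid is None:
            grid = np.arange(0.0, 5.0001, 0.01)
        grid = np.asarray(grid, dtype=float)
        prof = self.profile_loglike(grid, tol=tol)
        i = int(np.argmax(prof))
        # refit criteria at the winning grid point for a consistent result
        incr = self._default_increments()
        res = minimize(
            lambda z: -self.loglike(grid[i], z),
            incr, method="L-BFGS-B", bounds=[_INCR_BOUNDS] * incr.size,
            options={"ftol": tol, "maxiter": 300},
        )
        return self._make_results(grid[i], res.x, -res.fun, True, "grid search")


def fit_subject(trials: Iterable[TrialRecord], n_levels: int = 4) -> MetaDResults:
    """Convenience: tabulate one subject's trials and fit the meta-d' MLE."""
    return MetaDModel.from_trials(trials, n_levels=n_levels).fit()
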