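"""Type-1 signal detection theory for confidence-rated two-choice decisions.

A mental-rotation trial presents two 3-D shapes that are either *identical*
(rotatable into alignment; the signal class) or *different* (the noise
class).  The observer responds "identical"/"different" and rates confidence
on a discrete scale (4 points by default).  This module tabulates the
type-1 outcome counts (hits / misses / false alarms / correct rejections),
the response-conditional confidence counts that feed the meta-d' model, and
the metacognitive bias (mean confidence irrespective of accuracy).

Conventions
-----------
* stimulus/response labels are the strings ``"identical"`` and
  ``"different"``; "identical" is the signal class, so a hit is an
  identical pair called identical and a false alarm is a different pair
  called identical.
* equal-variance Gaussian SDT: d' = z(HR) - z(FAR),
  c = -(z(HR) + z(FAR)) / 2.
* extreme hit/false-alarm rates (0 or 1) are moved inward by 1/(2N) for the
  stimulus class with N trials before the normal-quantile transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

SIGNAL = "identical"
NOISE = "different"
STIMULI = (NOISE, SIGNAL)  # axis order used throughout: 0 = different, 1 = identical


@dataclass(frozen=True)
class TrialRecord:
    """One confidence-rated decision."""

    subject_id: str
    stimulus: str
    response: str
    confidence: int

    def __post_init__(self) -> None:
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if self.response not in STIMULI:
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def correct(self) -> bool:
        return self.stimulus == self.response


@dataclass(frozen=True)
class Type1Counts:
    """Hits / misses / false alarms / correct rejections for one subject."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def n_total(self) -> int:
        return self.n_signal + self.n_noise


@dataclass(frozen=True)
class Type2Counts:
    """Confidence counts split by stimulus class and response.

    ``counts[s, r, j]`` is the number of trials with stimulus ``STIMULI[s]``,
    response ``STIMULI[r]`` and confidence level ``j + 1``.  Collapsing over
    the confidence axis recovers the type-1 table.
    """

    counts: np.ndarray  # shape (2, 2, n_levels)
    n_levels: int = 4

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 2, self.n_levels):
            raise ValueError(f"counts must have shape (2, 2, {self.n_levels})")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    def to_type1(self) -> Type1Counts:
        c = self.counts.sum(axis=2)
        return Type1Counts(
            hits=int(round(c[1, 1])),
            misses=int(round(c[1, 0])),
            false_alarms=int(round(c[0, 1])),
            correct_rejections=int(round(c[0, 0])),
        )

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())


def _require_trials(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    return trials


def tabulate_type1(trials: Iterable[TrialRecord]) -> Type1Counts:
    """Partition one subject's trials into the four type-1 outcome cells."""
    trials = _require_trials(trials)
    hits = misses = fa = cr = 0
    for t in trials:
        if t.stimulus == SIGNAL:
            if t.response == SIGNAL:
                hits += 1
            else:
                misses += 1
        else:
            if t.response == SIGNAL:
                fa += 1
            else:
                cr += 1
    return Type1Counts(hits, misses, fa, cr)


def tabulate_type2(trials: Iterable[TrialRecord], n_levels: int = 4) -> Type2Counts:
    """Build the stimulus x response x confidence count table."""
    trials = _require_trials(trials)
    counts = np.zeros((2, 2, n_levels))
    for i, t in enumerate(trials):
        if not (1 <= t.confidence <= n_levels):
            raise ValueError(
                f"trial {i} (subject {t.subject_id}): confidence "
                f"{t.confidence} outside 1..{n_levels}"
            )
        s = STIMULI.index(t.stimulus)
        r = STIMULI.index(t.response)
        counts[s, r, t.confidence - 1] += 1
    return Type2Counts(counts, n_levels=n_levels)


def adjusted_rates(counts: Type1Counts) -> tuple[float, float]:
    """Hit and false-alarm rates with the 1/(2N) correction for 0 or 1."""
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("both stimulus classes must be present")

    def adjust(k: int, n: int) -> float:
        rate = k / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    return adjust(counts.hits, counts.n_signal), adjust(
        counts.false_alarms, counts.n_noise
    )


def compute_type1_sdt(counts: Type1Counts) -> tuple[float, float]:
    """Equal-variance d' and criterion c from a type-1 count table."""
    hr, far = adjusted_rates(counts)
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-0.5 * (zh + zf))


def compute_meta_bias(trials: Iterable[TrialRecord]) -> float:
    """Mean confidence over all trials, correct or not (over/under-confidence).

    On a 1..4 scale the midpoint is 2.5; a subject above the midpoint is
    classified as over-confident.
    """
    trials = _require_trials(trials)
    return float(np.mean([t.confidence for t in trials]))


def is_overconfident(meta_bias: float, n_levels: int = 4) -> bool:
    return meta_bias > (1 + n_levels) / 2


def trials_from_frame(df: pd.DataFrame) -> dict[str, list[TrialRecord]]:
    """Group a trials table (one row per trial) into per-subject records.

    Expects columns ``subject_id, stimulus, response, confidence``; extra
    columns (group, region, trial_index) are ignored here and recovered by
    the pipeline layer.
    """
    required = {"subject_id", "stimulus", "response", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    out: dict[str, list[TrialRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            TrialRecord(
                subject_id=str(row.subject_id),
                stimulus=str(row.stimulus),
                response=str(row.response),
                confidence=int(row.confidence),
            )
        )
    return out
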