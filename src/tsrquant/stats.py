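"""Cohort-level statistics for dichotomized TSR.

Category proportions, 2x2 association tests (Pearson chi-square
without continuity correction, Fisher's exact test with the two-sided
probability-mass rule), the Kaplan-Meier product-limit estimator, and
the Mantel-Cox log-rank test for time to biochemical recurrence.

The exact/asymptotic test machinery is delegated to scipy and
lifelines; this module fixes the conventions (no Yates correction,
probability-mass Fisher rule, exclusion of records without a follow-up
time) and the degenerate-input behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "ContingencyTable2x2",
    "cohort_proportions",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "km_estimate",
    "logrank_test",
    "NoEventsError",
]


class NoEventsError(ValueError):
    """Raised when a survival test is requested but no events occurred."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: months to biochemical recurrence or censoring.

    ``event`` is True for an observed recurrence, False for censoring.
    ``time`` of None means no usable follow-up; such records are
    excluded from Kaplan-Meier and log-rank analyses.
    """

    patient_id: str
    time: Optional[float]
    event: bool

    def __post_init__(self) -> None:
        if self.time is not None and self.time < 0:
            raise ValueError("follow-up time must be >= 0")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d of TSR category crossed with a binary variable."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def cohort_proportions(categories: Sequence[str]) -> dict:
    """Counts and percentages (2 decimals) per TSR category.

    Returns ``{category: {"count": n, "percent": p}}`` over the
    categories present, with percentages of the full cohort.
    """
    if len(categories) == 0:
        raise ValueError("empty category list")
    total = len(categories)
    out: dict = {}
    for cat in sorted(set(categories)):
        n = sum(1 for c in categories if c == cat)
        out[cat] = {"count": n, "percent": round(100.0 * n / total, 2)}
    return out


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (probability-mass rule).

    Sums hypergeometric probabilities, over tables with the observed
    margins, of every table no more probable than the observed one.
    A zero margin makes the table deterministic; p = 1 by convention.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its p-value, 1 df.

    Raises when any expected count is zero; use Fisher's exact test then.
    """
    arr = table.as_array()
    expected = sps.contingency.expected_freq(arr)
    if np.any(expected == 0):
        raise ValueError(
            "zero expected count: chi-square invalid, use fisher_exact_2x2"
        )
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def _usable(records: Sequence[SurvivalRecord]) -> list[SurvivalRecord]:
    usable = [r for r in records if r.time is not None]
    if any(r.time < 0 for r in usable):
        raise ValueError("negative follow-up time")
    return usable


def km_estimate(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit survival curve.

    Returns (times, survival) step-function coordinates starting at
    (0, 1). Records without a follow-up time are excluded.
    """
    usable = _usable(records)
    if not usable:
        raise ValueError("no records with follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in usable],
        event_observed=[r.event for r in usable],
    )
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return times, surv


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox log-rank statistic and p-value (chi-square, 1 df).

    Symmetric in the group order. Raises :class:`NoEventsError` when no
    event is observed in either group.
    """
    a, b = _usable(group_a), _usable(group_b)
    if not a or not b:
        raise ValueError("both groups must contain records with follow-up")
    if not any(r.event for r in a + b):
        raise NoEventsError("no events observed; log-rank test undefined")
    res = _ll_logrank(
        durations_A=[r.time for r in a],
        durations_B=[r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.test_statistic), float(res.p_value)
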