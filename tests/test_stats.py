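import math

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import chi2 as chi2_dist

from tsrquant.stats import (
    ContingencyTable2x2,
    NoEventsError,
    SurvivalRecord,
    chi_square_2x2,
    cohort_proportions,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
)


def rec(pid, time, event):
    return SurvivalRecord(patient_id=pid, time=time, event=event)


def enumerate_fisher(a, b, c, d):
    """Exact two-sided p by enumerating all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # hypergeometric mass of table with top-left cell x
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mantel_cox_statistic(times, events, group):
    """Direct O-E / V accumulation over distinct event times."""
    times, events, group = map(np.asarray, (times, events, group))
    o = e = v = 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = (events.astype(bool) & (times == t)).sum()
        d_a = (events.astype(bool) & (times == t) & (group == 0)).sum()
        o += d_a
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v if v > 0 else 0.0


class TestProportions:
    @pytest.mark.parametrize(
        "n_low, total, pct_low, pct_high",
        [(31, 72, 43.06, 56.94), (48, 209, 22.97, 77.03), (21, 42, 50.0, 50.0)],
    )
    def test_counts_and_percentages(self, n_low, total, pct_low, pct_high):
        cats = ["low"] * n_low + ["high"] * (total - n_low)
        out = cohort_proportions(cats)
        assert out["low"]["count"] == n_low
        assert out["low"]["percent"] == pytest.approx(pct_low, abs=0.005)
        assert out["high"]["percent"] == pytest.approx(pct_high, abs=0.005)
        assert out["low"]["percent"] + out["high"]["percent"] == pytest.approx(100, abs=0.01)

    def test_single_category(self):
        out = cohort_proportions(["high"] * 7)
        assert out == {"high": {"count": 7, "percent": 100.0}}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_proportions([])


class TestFisher:
    def test_diagonal_table(self):
        # only the two extreme tables are as improbable as (5,0,0,5)
        p = fisher_exact_2x2(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / comb(10, 5, exact=True), rel=1e-9)

    def test_balanced_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 0)) == 1.0

    def test_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            cells = rng.integers(0, 11, size=4)
            if cells.sum() == 0 or cells.sum() > 40:
                continue
            table = ContingencyTable2x2(*map(int, cells))
            arr = table.as_array()
            if np.any(arr.sum(0) == 0) or np.any(arr.sum(1) == 0):
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                enumerate_fisher(*map(int, cells)), rel=1e-7
            )


class TestChiSquare:
    def test_independence(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(25, 25, 25, 25))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed(self):
        # margins 40/40 each way -> expected 20 per cell; 4 * (10^2/20) = 20
        stat, p = chi_square_2x2(ContingencyTable2x2(30, 10, 10, 30))
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(chi2_dist.sf(20.0, 1))

    def test_doubling_doubles_statistic(self):
        s1, _ = chi_square_2x2(ContingencyTable2x2(12, 5, 7, 16))
        s2, _ = chi_square_2x2(ContingencyTable2x2(24, 10, 14, 32))
        assert s2 == pytest.approx(2 * s1)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_2x2(ContingencyTable2x2(5, 5, 0, 0))


class TestKaplanMeier:
    def test_all_censored_flat(self):
        times, surv = km_estimate([rec("a", 3, False), rec("b", 7, False)])
        assert np.all(surv == 1.0)

    def test_two_events(self):
        times, surv = km_estimate([rec("a", 1, True), rec("b", 2, True)])
        lookup = dict(zip(times, surv))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_censoring_decrements_risk_set_only(self):
        # event@1 (n=3): S=2/3; censor@2: no drop; event@3 (n=1): S=0
        times, surv = km_estimate(
            [rec("a", 1, True), rec("b", 2, False), rec("c", 3, True)]
        )
        lookup = dict(zip(times, surv))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_non_increasing_from_one(self):
        rng = np.random.default_rng(8)
        records = [
            rec(str(i), float(t), bool(e))
            for i, (t, e) in enumerate(
                zip(rng.exponential(10, 40), rng.integers(0, 2, 40))
            )
        ]
        times, surv = km_estimate(records)
        assert surv[0] == pytest.approx(1.0)
        assert np.all(np.diff(surv) <= 1e-12)

    def test_no_censoring_equals_empirical(self):
        t = [2.0, 5.0, 5.0, 9.0]
        times, surv = km_estimate([rec(str(i), x, True) for i, x in enumerate(t)])
        lookup = dict(zip(times, surv))
        assert lookup[2.0] == pytest.approx(3 / 4)
        assert lookup[5.0] == pytest.approx(1 / 4)
        assert lookup[9.0] == pytest.approx(0.0)

    def test_missing_time_excluded(self):
        times, surv = km_estimate(
            [rec("a", 1, True), rec("b", None, True), rec("c", 2, False)]
        )
        # only 2 usable records; event@1 out of n=2
        assert dict(zip(times, surv))[1.0] == pytest.approx(0.5)


class TestLogrank:
    GROUP_A = [rec("a1", 1, True), rec("a2", 3, True), rec("a3", 5, False)]
    GROUP_B = [rec("b1", 2, True), rec("b2", 4, True), rec("b3", 6, True)]

    def test_identical_groups_null(self):
        g = [rec("x", 1, True), rec("y", 2, False), rec("z", 3, True)]
        stat, p = logrank_test(g, list(g))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_example(self):
        # O_A = 2, E_A = 1/2 + 2/5 + 1/2 + 1/3, V = 1/4 + 6/25 + 1/4 + 2/9
        e_a = 0.5 + 0.4 + 0.5 + 1 / 3
        v = 0.25 + 0.24 + 0.25 + 2 / 9
        expected = (2 - e_a) ** 2 / v
        stat, p = logrank_test(self.GROUP_A, self.GROUP_B)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(chi2_dist.sf(expected, 1), rel=1e-9)

    def test_symmetric_in_group_order(self):
        s1, p1 = logrank_test(self.GROUP_A, self.GROUP_B)
        s2, p2 = logrank_test(self.GROUP_B, self.GROUP_A)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_no_events_signalled(self):
        with pytest.raises(NoEventsError):
            logrank_test([rec("a", 1, False)], [rec("b", 2, False)])

    def test_matches_direct_accumulation_random(self):
        rng = np.random.default_rng(99)
        times = rng.exponential(10, 30).round(2)
        events = rng.integers(0, 2, 30).astype(bool)
        group = rng.integers(0, 2, 30)
        a = [rec(str(i), t, bool(e)) for i, (t, e, g) in enumerate(zip(times, events, group)) if g == 0]
        b = [rec(str(i), t, bool(e)) for i, (t, e, g) in enumerate(zip(times, events, group)) if g == 1]
        stat, _ = logrank_test(a, b)
        assert stat == pytest.approx(mantel_cox_statistic(times, events, group), rel=1e-9)

    def test_permutation_oracle(self):
        # chi-square p vs a relabeling null on a 20-patient cohort; the
        # tolerance covers Monte-Carlo and asymptotic-approximation error
        rng = np.random.default_rng(17)
        times = rng.exponential(12, 20).round(3)
        events = rng.random(20) < 0.7
        group = np.array([0] * 10 + [1] * 10)
        a = [rec(str(i), float(t), bool(e)) for i, (t, e, g) in enumerate(zip(times, events, group)) if g == 0]
        b = [rec(str(i), float(t), bool(e)) for i, (t, e, g) in enumerate(zip(times, events, group)) if g == 1]
        stat, p = logrank_test(a, b)
        perm_stats = np.empty(10_000)
        for k in range(10_000):
            perm = rng.permutation(group)
            perm_stats[k] = mantel_cox_statistic(times, events, perm)
        p_perm = float(np.mean(perm_stats >= stat - 1e-12))
        assert abs(p - p_perm) < 0.05
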