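"""Contingency tables, ROR/PRR/BCPNN, thresholds, strong conditions, ranking.

Formula checks compare against single-purpose oracles written out in this
file directly from the definitions, independent of the implementation path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerskit.disprop import (
    ContingencyTable,
    SignalStats,
    build_tables,
    classify_signal,
    compute_bcpnn,
    compute_prr,
    compute_ror,
    rank_top_k,
    strong_condition,
)
from faerskit.disprop import SignalRow

from conftest import mk_case


# ---------------------------------------------------------------------------
# independent single-purpose oracles


def oracle_ror(a, b, c, d):
    ror = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_chi2_yates(a, b, c, d):
    n = a + b + c + d
    dev = abs(a * d - b * c)
    num = max(dev - n / 2, 0.0)
    return n * num * num / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    ab, ac = a + b, a + c
    g = (n + 2) * (n + 2) / ((ab + 1) * (ac + 1))
    e_ic = math.log2((a + 1) * (n + 2) * (n + 2) / ((n + g) * (ab + 1) * (ac + 1)))
    v_ic = (
        (n - a + g - 1) / ((a + 1) * (1 + n + g))
        + (n - ab + 1) / ((ab + 1) * (3 + n))
        + (n - ac + 1) / ((ac + 1) * (3 + n))
    ) / math.log(2) ** 2
    return e_ic, e_ic - 2 * math.sqrt(v_ic)


# ---------------------------------------------------------------------------


class TestContingencyTable:
    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_expected_count(self):
        t = ContingencyTable(10, 20, 30, 6000)
        assert t.expected == pytest.approx(30 * 40 / 6060)


class TestBuildTables:
    def test_hand_counted_example(self):
        cases = [
            mk_case("1", "D", ["E"]),
            mk_case("2", "D", ["E"]),
            mk_case("3", "D", ["other"]),
            mk_case("4", "X", ["E"]),
            mk_case("5", "X", ["other"]),
        ]
        t = build_tables(cases, "D")["E"]
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)

    def test_pt_unreported_in_cohort(self):
        cases = [mk_case("1", "D", ["other"]), mk_case("2", "X", ["E"])]
        t = build_tables(cases, "D")["E"]
        assert (t.a, t.b) == (0, 1)

    def test_empty_case_list(self):
        assert build_tables([], "D") == {}

    def test_margins_conserved_on_synthetic(self, small_cases):
        """For every PT: a+b = cohort size, a+c = PT total, N constant."""
        for drug in ("pitolisant", "modafinil"):
            tables = build_tables(small_cases, drug)
            cohort = sum(1 for c in small_cases if c.in_cohort(drug))
            for pt, t in tables.items():
                assert t.a + t.b == cohort
                assert t.a + t.c == sum(1 for c in small_cases if pt in c.events)
                assert t.n == len(small_cases)

    def test_brute_force_oracle_on_synthetic(self, small_cases):
        """Every cell equals an O(cases x PTs) nested-loop recount."""
        drug = "sodium_oxybate"
        tables = build_tables(small_cases, drug)
        for pt, t in tables.items():
            a = b = c = d = 0
            for case in small_cases:
                inc, ev = case.in_cohort(drug), pt in case.events
                if inc and ev:
                    a += 1
                elif inc:
                    b += 1
                elif ev:
                    c += 1
                else:
                    d += 1
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d), pt


class TestRor:
    def test_symmetric_table(self):
        r = compute_ror(ContingencyTable(1, 1, 1, 1))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_worked_example(self):
        r = compute_ror(ContingencyTable(10, 20, 30, 6000))
        e_ror, e_lo, e_hi = oracle_ror(10, 20, 30, 6000)
        assert r.ror == pytest.approx(e_ror, rel=1e-12)
        assert r.ci_low == pytest.approx(e_lo, rel=1e-12)
        assert r.ci_high == pytest.approx(e_hi, rel=1e-12)
        assert (round(r.ci_low, 1), round(r.ci_high, 1)) == (43.2, 231.5)

    def test_a_zero_short_circuits(self):
        r = compute_ror(ContingencyTable(0, 5, 5, 100))
        assert r.ror == 0.0
        assert "undefined_ci" in r.flags
        assert math.isnan(r.ci_low)

    def test_zero_cell_continuity_corrected(self):
        r = compute_ror(ContingencyTable(3, 0, 5, 100))
        assert "continuity_corrected" in r.flags
        assert r.ror == pytest.approx((3.5 * 100.5) / (0.5 * 5.5), rel=1e-12)


class TestPrr:
    def test_symmetric_table(self):
        r = compute_prr(ContingencyTable(1, 1, 1, 1))
        assert r.prr == pytest.approx(1.0)
        assert r.chi2 == 0.0

    def test_worked_example(self):
        r = compute_prr(ContingencyTable(10, 20, 30, 6000))
        assert r.prr == pytest.approx((10 / 30) / (30 / 6030), rel=1e-12)
        assert r.chi2 == pytest.approx(oracle_chi2_yates(10, 20, 30, 6000), rel=1e-12)

    def test_a_zero(self):
        r = compute_prr(ContingencyTable(0, 10, 10, 100))
        assert r.prr == 0.0

    def test_c_zero_correction(self):
        r = compute_prr(ContingencyTable(3, 7, 0, 100))
        assert "continuity_corrected" in r.flags
        assert r.prr == pytest.approx((3.5 / 11) / (0.5 / 101), rel=1e-12)


class TestBcpnn:
    def test_independence_limit(self):
        r = compute_bcpnn(ContingencyTable(100, 9900, 9900, 980100))
        assert abs(r.ic) < 0.02

    def test_asymptotic_log2_rr(self):
        # margins fixed at RR = 8, a = 1e5: IC -> log2 8 = 3
        a, ab, ac, n = 100_000, 1_000_000, 1_000_000, 80_000_000
        t = ContingencyTable(a, ab - a, ac - a, n - ab - ac + a)
        r = compute_bcpnn(t)
        assert abs(r.ic - 3.0) < 0.01

    def test_formula_oracle(self):
        r = compute_bcpnn(ContingencyTable(10, 20, 30, 6000))
        e_ic, e_lo = oracle_ic(10, 20, 30, 6000)
        assert r.ic == pytest.approx(e_ic, rel=1e-12)
        assert r.ic_minus_2sd == pytest.approx(e_lo, rel=1e-12)

    def test_defined_at_a_zero(self):
        r = compute_bcpnn(ContingencyTable(0, 10, 10, 100))
        assert math.isfinite(r.ic)

    def test_null_calibration_at_expected_20(self):
        """Independence sampling (RR=1, N=1e6, E[a]=20): IC-2SD exceeds 0 in
        at most 5% of tables (nominal one-sided ~2.5%)."""
        rng = np.random.default_rng(2024)
        p_drug, p_event, n = 0.005, 0.004, 1_000_000
        probs = [
            p_drug * p_event,
            p_drug * (1 - p_event),
            (1 - p_drug) * p_event,
            (1 - p_drug) * (1 - p_event),
        ]
        draws = rng.multinomial(n, probs, size=600)
        hits = 0
        for a, b, c, d in draws:
            if compute_bcpnn(ContingencyTable(int(a), int(b), int(c), int(d))).ic_minus_2sd > 0:
                hits += 1
        assert hits / 600 <= 0.05


class TestOracleEquivalence:
    def test_random_tables_match_formula_oracles(self):
        """200 random non-degenerate tables at 1e-10 relative (the full
        1,000-table sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(0, 501, size=4))
            if min(a, b, c, d) == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            e_ror, e_lo, e_hi = oracle_ror(a, b, c, d)
            r = compute_ror(t)
            assert r.ror == pytest.approx(e_ror, rel=1e-10)
            assert r.ci_low == pytest.approx(e_lo, rel=1e-10)
            assert r.ci_high == pytest.approx(e_hi, rel=1e-10)
            p = compute_prr(t)
            assert p.prr == pytest.approx(oracle_prr(a, b, c, d), rel=1e-10)
            assert p.chi2 == pytest.approx(oracle_chi2_yates(a, b, c, d), rel=1e-10, abs=1e-10)
            ic, lo = oracle_ic(a, b, c, d)
            bc = compute_bcpnn(t)
            assert bc.ic == pytest.approx(ic, rel=1e-10, abs=1e-12)
            assert bc.ic_minus_2sd == pytest.approx(lo, rel=1e-10, abs=1e-12)
            checked += 1


class TestMonotonicity:
    @given(
        a=st.integers(1, 200),
        delta=st.integers(1, 100),
        b=st.integers(1, 500),
        c=st.integers(1, 500),
        d=st.integers(1, 5000),
    )
    def test_ror_prr_nondecreasing_in_a(self, a, delta, b, c, d):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + delta, b, c, d)
        assert compute_ror(t2).ror >= compute_ror(t1).ror
        assert compute_prr(t2).prr >= compute_prr(t1).prr

    @given(
        a=st.integers(1, 50),
        delta=st.integers(1, 50),
        b=st.integers(100, 500),
        c=st.integers(100, 500),
        d=st.integers(1000, 50000),
    )
    def test_ic_nondecreasing_in_a_sparse_regime(self, a, delta, b, c, d):
        """IC grows with a while the pair stays sparse relative to its
        margins (a'^2 <= b*c). Outside that regime the observed/expected
        ratio aN/((a+b)(a+c)) itself is non-monotone in a, so no blanket
        claim is possible."""
        from hypothesis import assume

        assume((a + delta) ** 2 <= b * c)
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + delta, b, c, d)
        assert compute_bcpnn(t2).ic >= compute_bcpnn(t1).ic


def _stats(**kw) -> SignalStats:
    base = dict(
        ror=5.0, ror_ci_low=2.0, ror_ci_high=10.0, prr=5.0, chi2=50.0,
        ic=1.5, ic_minus_2sd=0.5, ebgm=4.0, eb05=3.0,
    )
    base.update(kw)
    return SignalStats(**base)


class TestClassifySignal:
    def test_a_below_3_gates_everything(self):
        fl = classify_signal(_stats(ror=1e6, ror_ci_low=1e5, prr=1e6, chi2=1e6), a=2)
        assert not fl.signal
        assert not fl.ror_sig and not fl.prr_sig and not fl.bcpnn_sig
        # MGPS has no case-count gate of its own
        assert fl.mgps_sig

    def test_prr_thresholds_inclusive(self):
        fl = classify_signal(_stats(prr=2.0, chi2=4.0), a=3)
        assert fl.prr_sig and fl.signal

    def test_ror_ci_boundary_strict(self):
        fl = classify_signal(_stats(ror_ci_low=1.0), a=100)
        assert not fl.ror_sig and not fl.signal

    def test_ic_minus_2sd_boundary_strict(self):
        assert not classify_signal(_stats(ic_minus_2sd=0.0), a=100).bcpnn_sig

    def test_eb05_boundary_strict(self):
        assert not classify_signal(_stats(eb05=2.0), a=100).mgps_sig

    def test_any_policy(self):
        fl = classify_signal(_stats(eb05=1.0), a=3, policy="any")
        assert fl.signal and not fl.mgps_sig

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            classify_signal(_stats(), a=3, policy="bogus")


class TestStrongCondition:
    def test_condition_a(self):
        r = strong_condition(_stats(ror=11, prr=12, ebgm=10.5, ic=2), other_ics=[2.5])
        assert r.label == "A"

    def test_condition_b(self):
        r = strong_condition(_stats(ror=5, prr=5, ebgm=5, ic=3.2), other_ics=[3.5])
        assert r.label == "B"

    def test_condition_c_beats_d(self):
        r = strong_condition(_stats(ror=20, prr=20, ebgm=15, ic=3.5), other_ics=[1.0])
        assert r.label == "C" and r.cond_d

    def test_condition_d_strict_and_vacuous(self):
        assert strong_condition(_stats(ic=2.0), other_ics=[2.0]).label == "none"
        assert strong_condition(_stats(ic=2.0), other_ics=[1.9]).label == "D"
        assert strong_condition(_stats(ic=2.0), other_ics=[]).cond_d  # vacuous


class TestRankTopK:
    def _row(self, pt, a, ic):
        return SignalRow(drug="D", pt=pt, a=a, stats=_stats(ic=ic))

    def test_tie_break_order(self):
        rows = [self._row("first", 10, 1.0), self._row("second", 9, 3.0), self._row("third", 9, 2.0)]
        got = rank_top_k(list(reversed(rows)), 3)
        assert [r.pt for r in got] == ["first", "second", "third"]

    def test_k_larger_than_list(self):
        rows = [self._row("x", 5, 1.0)]
        assert rank_top_k(rows, 15) == rows

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        rows = [
            self._row(f"pt{i}", int(rng.integers(1, 20)), float(rng.normal()))
            for i in range(40)
        ]
        oracle = sorted(rows, key=lambda r: (-r.a, -r.stats.ic, r.pt))[:15]
        assert rank_top_k(rows, 15) == oracle
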