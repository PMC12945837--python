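"""Disproportionality statistics: worked values, identities, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvscreen import (
    BCPNNPriors,
    ContingencyTable,
    ThresholdConfig,
    compute_bcpnn,
    compute_ebgm,
    compute_metrics,
    compute_prr,
    compute_ror,
    evaluate_flags,
    reconstruct_table_from_stats,
)

cells = st.integers(min_value=1, max_value=100_000)


def table(a, b, c, d):
    return ContingencyTable(a, b, c, d)


class TestWorkedValues:
    def test_independent_table_is_null_for_every_method(self):
        t = table(10, 10, 10, 10)
        ror, lo, hi = compute_ror(t)
        assert ror == pytest.approx(1.0)
        assert lo < 1 < hi
        prr, _, _, chi2 = compute_prr(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        ic, _, _, _ = compute_bcpnn(t)
        assert ic == pytest.approx(0.0)
        ebgm, _, _ = compute_ebgm(t)
        assert ebgm == pytest.approx(1.0)

    def test_hand_evaluated_odds_ratio(self):
        ror, _, _ = compute_ror(table(6, 4, 3, 7))
        assert ror == pytest.approx(6 * 7 / (4 * 3))

    def test_chi2_zero_when_ad_equals_bc(self):
        _, _, _, chi2 = compute_prr(table(2, 4, 3, 6))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_gives_reason_coded_nan(self):
        m = compute_metrics(table(3, 0, 5, 7))
        assert np.isnan(m.ror) and np.isnan(m.ror_lo)
        assert "zero_cell_b" in m.reasons
        # the undefined ROR never flags; PRR stays defined for b=0
        assert not m.flags["ror"]
        assert np.isfinite(m.prr)

    def test_continuity_correction_recovers_finite_ror(self):
        m = compute_metrics(table(3, 0, 5, 7), continuity_correction=True)
        assert np.isfinite(m.ror)
        expected = (3.5 * 7.5) / (0.5 * 5.5)
        assert m.ror == pytest.approx(expected)
        assert m.reasons == ("continuity_correction",)


class TestPublishedRow:
    """The strongest published signal row is fully reconstructable from its
    own printed statistics; every method must reproduce the printed bounds."""

    @pytest.fixture()
    def irr_table(self):
        return reconstruct_table_from_stats(581, 2245 - 581, 354.61, 150249)

    def test_ror_and_ci(self, irr_table):
        ror, lo, hi = compute_ror(irr_table)
        assert ror == pytest.approx(354.61, abs=0.05)
        assert lo == pytest.approx(322.53, abs=0.05)
        assert hi == pytest.approx(389.89, abs=0.05)

    def test_prr_ci_and_chi2(self, irr_table):
        prr, lo, hi, chi2 = compute_prr(irr_table)
        assert prr == pytest.approx(263.10, abs=0.05)
        assert lo == pytest.approx(245.19, abs=0.05)
        assert chi2 == pytest.approx(150249, rel=1e-4)

    def test_bcpnn_ic_and_lower_bound(self, irr_table):
        ic, e_ic, v_ic, ic025 = compute_bcpnn(irr_table, BCPNNPriors())
        assert ic == pytest.approx(8.02, abs=0.01)
        assert ic025 == pytest.approx(7.36, abs=0.01)

    def test_ebgm_and_lower_bound(self, irr_table):
        ebgm, lo, _ = compute_ebgm(irr_table)
        assert ebgm == pytest.approx(260.33, abs=0.05)
        assert lo == pytest.approx(236.78, abs=0.05)

    def test_all_five_methods_flag(self, irr_table):
        m = compute_metrics(irr_table)
        assert all(m.flags.values())


class TestFlags:
    def test_small_a_never_flags_ror(self):
        m = compute_metrics(table(2, 5, 10, 1000))
        assert not m.flags["ror"] and not m.flags["prr"]

    def test_mhra_requires_prr_at_least_two(self):
        # strong chi2 but PRR below 2
        m = compute_metrics(table(190, 810, 100_000, 900_000))
        assert m.prr < 2 and m.chi2 > 4
        assert not m.flags["mhra"]

    def test_mhra_all_three_conditions(self):
        m = compute_metrics(table(50, 50, 100, 900))
        assert m.prr >= 2 and m.chi2 >= 4 and m.a >= 3
        assert m.flags["mhra"]

    def test_evaluate_flags_respects_custom_thresholds(self):
        m = compute_metrics(table(4, 10, 40, 1000))
        strict = evaluate_flags(m, cfg=ThresholdConfig(min_a=5))
        assert not strict["ror"]

    def test_priors_must_be_positive(self):
        with pytest.raises(Exception):
            BCPNNPriors(alpha=-1)


class TestProperties:
    @settings(derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic_equals_log2_ebgm(self, a, b, c, d):
        t = table(a, b, c, d)
        ic, _, _, _ = compute_bcpnn(t)
        ebgm, _, _ = compute_ebgm(t)
        assert abs(ic - np.log2(ebgm)) < 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ror_prr_ordering_law(self, a, b, c, d):
        t = table(a, b, c, d)
        ror, _, _ = compute_ror(t)
        prr, _, _, _ = compute_prr(t)
        lhs = ror >= prr
        rhs = d / (c + d) >= b / (a + b)
        assert lhs == rhs

    @settings(derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_invariant_under_double_transposition(self, a, b, c, d):
        _, _, _, chi2 = compute_prr(table(a, b, c, d))
        _, _, _, chi2_t = compute_prr(table(d, c, b, a))
        assert chi2 == pytest.approx(chi2_t, rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(1, 500), b=cells, c=cells, d=cells)
    def test_ror_prr_strictly_monotone_in_a(self, a, b, c, d):
        lo_t, hi_t = table(a, b, c, d), table(a + 1, b, c, d)
        assert compute_ror(hi_t)[0] > compute_ror(lo_t)[0]
        assert compute_prr(hi_t)[0] > compute_prr(lo_t)[0]

    @settings(derandomize=True, max_examples=100)
    @given(a=st.integers(1, 200), k=st.integers(20, 500),
           c_extra=st.integers(0, 10_000), d=st.integers(1, 10_000_000))
    def test_ic_ebgm_monotone_in_a_for_rare_events(self, a, k, c_extra, d):
        # IC/EBGM are relative reporting ratios; a+1 also inflates both
        # margins, so monotonicity holds only when the event is rare among
        # the exposed (b >> a) and the comparator carries the event (c >= a)
        b, c = a * k, a + c_extra
        lo_t, hi_t = table(a, b, c, d), table(a + 1, b, c, d)
        assert compute_bcpnn(hi_t)[0] > compute_bcpnn(lo_t)[0]
        assert compute_ebgm(hi_t)[0] > compute_ebgm(lo_t)[0]

    @settings(derandomize=True, max_examples=100)
    @given(a=st.integers(1, 1000), b=st.integers(1, 20_000),
           c=st.integers(1, 50_000))
    def test_shrinkage_pulls_e_ic_below_ic(self, a, b, c):
        # sparse signal tables: a << N
        d = 10_000_000
        t = table(a, b, c, d)
        ic, e_ic, _, _ = compute_bcpnn(t)
        ebgm, _, _ = compute_ebgm(t)
        if ebgm > 1:
            assert e_ic <= ic

    def test_interval_orderings(self):
        m = compute_metrics(table(30, 70, 400, 9500))
        assert m.ror_lo <= m.ror <= m.ror_hi
        assert m.prr_lo <= m.prr <= m.prr_hi
        assert m.ebgm_lo <= m.ebgm <= m.ebgm_hi
        assert m.ic_minus_2sd <= m.e_ic


class TestReconstruction:
    def test_round_trips_its_own_statistics(self):
        t0 = ContingencyTable(50, 950, 5000, 994_000)
        ror, _, _ = compute_ror(t0)
        _, _, _, chi2 = compute_prr(t0)
        t1 = reconstruct_table_from_stats(t0.a, t0.b, ror, chi2)
        assert t1.cells() == t0.cells()

    def test_rejects_unbracketable_target(self):
        with pytest.raises(Exception):
            reconstruct_table_from_stats(10, 10, 2.0, 1e12)
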