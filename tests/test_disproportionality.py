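"""Detector formulas, significance gates and intensity bands.

The reference oracle below re-evaluates every published formula with plain
``math`` calls, independently of the vectorised implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.contingency import ContingencyTable
from pvsignal.disproportionality import (
    bcpnn_statistic,
    compute_statistics,
    evaluate_significance,
    grade_intensity,
    mgps_statistic,
    prr_statistic,
    ror_statistic,
    statistics_frame,
)


def oracle(a, b, c, d):
    """Straight-line evaluation of the four detectors' printed formulas."""
    T = a + b + c + d
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = a * d / (b * c)
    prr = a * (c + d) / (c * (a + b))
    chi2 = (a * d - b * c) ** 2 * T / ((a + b) * (c + d) * (a + c) * (b + d))
    ratio = a * T / ((a + c) * (a + b))
    ic = math.log2(ratio)
    out = {
        "ror": ror,
        "ror_low": math.exp(math.log(ror) - 1.96 * s),
        "ror_high": math.exp(math.log(ror) + 1.96 * s),
        "prr": prr,
        "prr_low": math.exp(math.log(prr) - 1.96 * s),
        "prr_high": math.exp(math.log(prr) + 1.96 * s),
        "chi2": chi2,
        "ic": ic,
        "ic025": math.exp(math.log(ic) - 1.96 * s) if ic > 0 else float("nan"),
        "ebgm": ratio,
        "ebgm05": math.exp(math.log(ratio) - 1.64 * s),
        "shared_se": s,
    }
    return out


WORKED = ContingencyTable(10, 90, 100, 9900)


class TestPointEstimates:
    def test_worked_example_matches_hand_evaluation(self):
        s = compute_statistics(WORKED)
        expect = oracle(10, 90, 100, 9900)
        for key, val in expect.items():
            assert getattr(s, key) == pytest.approx(val, rel=1e-12), key
        # magnitudes of the hand-derived reference values
        assert s.ror == pytest.approx(11.000, abs=1e-3)
        assert s.ror_low == pytest.approx(5.559, abs=1e-3)
        assert s.ror_high == pytest.approx(21.766, rel=1e-3)
        assert s.prr == pytest.approx(10.000, abs=1e-3)
        assert s.chi2 == pytest.approx(74.45, abs=0.01)
        assert s.ic == pytest.approx(3.199, abs=1e-3)
        assert s.ic025 == pytest.approx(1.617, abs=1e-3)
        assert s.ebgm == pytest.approx(9.182, abs=1e-3)
        assert s.ebgm05 == pytest.approx(5.187, abs=1e-3)

    def test_balanced_table_is_null(self):
        s = compute_statistics(ContingencyTable(5, 5, 5, 5))
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.chi2 == pytest.approx(0.0)
        assert s.ic == pytest.approx(0.0)
        assert s.ebgm == pytest.approx(1.0)
        assert not math.isfinite(s.ic025)  # interval undefined at IC = 0

    def test_zero_cell_flags_undefined(self):
        s = compute_statistics(ContingencyTable(0, 10, 10, 100))
        assert not s.defined["ror"]
        assert not s.defined["ic"]
        assert not s.defined["ebgm05"]
        assert math.isnan(s.ror)
        # zero cells never raise, and the pair is never significant
        assert not evaluate_significance(s).combined

    def test_continuity_correction_defines_zero_cell_tables(self):
        s = compute_statistics(ContingencyTable(0, 10, 10, 100),
                               continuity_correction=True)
        expect = oracle(0.5, 10.5, 10.5, 100.5)
        assert s.ror == pytest.approx(expect["ror"], rel=1e-12)
        assert s.n == 0  # n reports the raw a cell

    def test_scalar_wrappers_agree_with_full_computation(self):
        s = compute_statistics(WORKED)
        assert ror_statistic(WORKED) == pytest.approx((s.ror, s.ror_low, s.ror_high))
        assert prr_statistic(WORKED) == pytest.approx(
            (s.prr, s.prr_low, s.prr_high, s.chi2))
        assert bcpnn_statistic(WORKED) == pytest.approx((s.ic, s.ic025))
        assert mgps_statistic(WORKED) == pytest.approx((s.ebgm, s.ebgm05))

    def test_additive_bcpnn_interval_flag(self):
        s = compute_statistics(WORKED, bcpnn_additive_interval=True)
        expect = s.ic - 1.96 * s.shared_se / math.log(2)
        assert s.ic025 == pytest.approx(expect, rel=1e-12)

    def test_frame_matches_scalar_path(self):
        rng = np.random.default_rng(7)
        tables = [ContingencyTable(*map(int, rng.integers(1, 500, 4)), "D", f"P{i}")
                  for i in range(20)]
        frame = statistics_frame(tables)
        for i, t in enumerate(tables):
            s = compute_statistics(t)
            assert frame.loc[i, "ror"] == pytest.approx(s.ror, rel=1e-12, nan_ok=True)
            assert frame.loc[i, "ebgm05"] == pytest.approx(s.ebgm05, rel=1e-12)


class TestProperties:
    @given(st.integers(1, 2000), st.integers(1, 2000),
           st.integers(1, 2000), st.integers(1, 2000))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_identity(self, a, b, c, d):
        s = compute_statistics(ContingencyTable(a, b, c, d))
        expect = oracle(a, b, c, d)
        for key in ("ror", "prr", "chi2", "ebgm", "ebgm05", "shared_se"):
            assert getattr(s, key) == pytest.approx(expect[key], rel=1e-10), key
        assert 2.0 ** s.ic == pytest.approx(s.ebgm, rel=1e-13)

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_interval_ordering(self, a, b, c, d):
        s = compute_statistics(ContingencyTable(a, b, c, d))
        assert s.ror_low < s.ror < s.ror_high
        assert s.prr_low < s.prr < s.prr_high
        assert s.ebgm05 < s.ebgm

    @given(st.integers(2, 300), st.integers(1, 300),
           st.integers(1, 300), st.integers(1, 300))
    @settings(max_examples=100, deadline=None)
    def test_ror_prr_strictly_monotone_in_a(self, a, b, c, d):
        lo = compute_statistics(ContingencyTable(a - 1, b, c, d))
        hi = compute_statistics(ContingencyTable(a, b, c, d))
        assert hi.ror > lo.ror
        assert hi.prr > lo.prr

    @given(st.integers(2, 50), st.integers(100, 500),
           st.integers(100, 500), st.integers(1000, 10000))
    @settings(max_examples=100, deadline=None)
    def test_ic_ebgm_monotone_when_a_is_small_against_margins(self, a, b, c, d):
        # The observed/expected ratio aT/((a+c)(a+b)) is NOT globally monotone
        # in a (it falls once a^2 > bc, e.g. (2,1,1,5) -> (3,1,1,5)); in the
        # signal-mining regime, where the drug and event margins dwarf a, it
        # strictly increases.
        lo = compute_statistics(ContingencyTable(a - 1, b, c, d))
        hi = compute_statistics(ContingencyTable(a, b, c, d))
        assert hi.ic > lo.ic
        assert hi.ebgm > lo.ebgm

    @given(st.integers(1, 300), st.integers(1, 300),
           st.integers(1, 300), st.integers(1, 300))
    @settings(max_examples=100, deadline=None)
    def test_ic_scale_invariant_and_chi2_symmetric(self, a, b, c, d):
        s1 = compute_statistics(ContingencyTable(a, b, c, d))
        s2 = compute_statistics(ContingencyTable(2 * a, 2 * b, 2 * c, 2 * d))
        assert s2.ic == pytest.approx(s1.ic, rel=1e-12)
        swapped = compute_statistics(ContingencyTable(d, c, b, a))
        assert swapped.chi2 == pytest.approx(s1.chi2, rel=1e-12)


class TestSignificance:
    def test_worked_example_all_four_positive(self):
        decision = evaluate_significance(compute_statistics(WORKED))
        assert decision.significant == {m: True for m in ("ror", "prr", "bcpnn", "mgps")}
        assert decision.combined

    def test_fewer_than_three_reports_never_signals(self):
        # strong disproportionality but only 2 reports
        decision = evaluate_significance(compute_statistics(
            ContingencyTable(2, 10, 5, 10000)))
        assert not any(decision.significant.values())
        assert not decision.combined

    def test_balanced_table_nonsignificant(self):
        decision = evaluate_significance(compute_statistics(ContingencyTable(5, 5, 5, 5)))
        assert not any(decision.significant.values())

    def test_prr_gate_needs_ratio_and_chi2(self):
        # disproportionate but PRR < 2: ROR may pass while PRR must not
        s = compute_statistics(ContingencyTable(60, 940, 400, 9600))
        decision = evaluate_significance(s)
        assert s.prr < 2
        assert not decision.significant["prr"]
        assert not decision.combined

    def test_mgps_gate_is_on_the_lower_bound(self):
        s = compute_statistics(ContingencyTable(12, 400, 100, 9000))
        decision = evaluate_significance(s)
        assert decision.significant["mgps"] == (s.ebgm05 > 2)


class TestIntensity:
    def test_ror_bands(self):
        def grade_for(ror_value_table):
            s = compute_statistics(ror_value_table)
            return grade_intensity(s, evaluate_significance(s))

        strong = grade_for(ContingencyTable(12, 88, 180, 99720))   # ROR ~ 75
        assert strong["ror"] == "strong"
        medium = grade_for(WORKED)                                 # ROR = 11
        assert medium["ror"] == "medium"
        weak = grade_for(ContingencyTable(60, 940, 200, 9800))     # ROR ~ 3.1
        assert weak["ror"] == "weak"

    def test_bcpnn_band_on_ic025(self):
        s = compute_statistics(ContingencyTable(2444, 16000, 14000, 2500000))
        decision = evaluate_significance(s)
        grades = grade_intensity(s, decision)
        assert s.ic025 > 3
        assert grades["bcpnn"] == "strong"

    def test_nonsignificant_grades_none_regardless_of_magnitude(self):
        s = compute_statistics(ContingencyTable(2, 1, 1, 10000))  # n < 3
        decision = evaluate_significance(s)
        assert grade_intensity(s, decision) == {
            "ror": "none", "prr": "none", "bcpnn": "none", "mgps": "none"}

    def test_value_at_lower_edge_grades_none(self):
        # significant MGPS but EBGM05 graded none at or below 2 is impossible
        # (the gate is EBGM05 > 2); check the ROR edge instead: ror <= 2 -> none
        s = compute_statistics(ContingencyTable(100, 1000, 500, 9500))
        decision = evaluate_significance(s)
        grades = grade_intensity(s, decision)
        assert s.ror <= 2.1
        assert grades["ror"] in ("none", "weak")
        if s.ror <= 2:
            assert grades["ror"] == "none"
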