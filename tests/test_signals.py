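import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from faersig import signals as sg

T = sg.ContingencyTable
REF = T(10, 90, 100, 9900)  # hand-checked reference table


class TestRor:
    def test_reference_table(self):
        r = sg.ror_stats(REF)
        assert r.ror == pytest.approx(11.0)
        # exp(ln 11 -/+ 1.96*sqrt(1/10+1/90+1/100+1/9900))
        assert r.lo == pytest.approx(5.559, abs=0.01)
        assert r.hi == pytest.approx(21.766, abs=0.01)
        assert r.flag and not r.corrected

    def test_proportional_rows_null(self):
        r = sg.ror_stats(T(5, 5, 5, 5))
        assert r.ror == pytest.approx(1.0)
        assert not r.flag

    def test_minimum_count_rule(self):
        # strong association but only 2 target cases -> never flagged
        r = sg.ror_stats(T(2, 8, 10, 9980))
        assert r.lo > 1
        assert not r.flag

    def test_lower_bound_strictly_greater(self):
        r = sg.ror_stats(REF)
        at_bound = sg.Thresholds(ror_lower=r.lo)
        assert not sg.ror_stats(REF, at_bound).flag


class TestPrr:
    def test_reference_table(self):
        p = sg.prr_stats(REF)
        assert p.prr == pytest.approx(10.0)
        assert p.chi2 == pytest.approx(74.447, abs=0.05)
        assert p.flag

    def test_proportional_rows_null(self):
        p = sg.prr_stats(T(1, 9, 10, 90))
        assert p.prr == pytest.approx(1.0)
        assert p.chi2 == pytest.approx(0.0, abs=1e-12)
        assert not p.flag

    def test_thresholds_inclusive(self):
        p = sg.prr_stats(REF)
        exact = sg.Thresholds(prr=p.prr, chi2=p.chi2)
        assert sg.prr_stats(REF, exact).flag  # >= comparisons at the boundary

    def test_yates_reduces_chi2(self):
        assert sg.prr_stats(REF, yates=True).chi2 < sg.prr_stats(REF).chi2

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_chi2_matches_textbook_oracle(self, cells):
        """Closed-form chi2 equals the observed-vs-expected Pearson statistic."""
        a, b, c, d = cells
        ours = sg.prr_stats(T(a, b, c, d)).chi2
        oracle = chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_yates_matches_scipy_correction(self):
        ours = sg.prr_stats(T(8, 22, 14, 56), yates=True).chi2
        oracle = chi2_contingency([[8, 22], [14, 56]], correction=True).statistic
        assert ours == pytest.approx(oracle, abs=1e-9)


class TestBcpnn:
    def test_reference_table(self):
        b = sg.bcpnn_stats(REF)
        assert b.ic == pytest.approx(math.log2(9.1818), abs=5e-4)

    def test_proportional_rows_null(self):
        b = sg.bcpnn_stats(T(1, 9, 10, 90))
        assert b.ic == pytest.approx(0.0, abs=1e-12)
        assert not b.flag

    def test_a_zero_undefined(self):
        b = sg.bcpnn_stats(T(0, 100, 10, 890))
        assert math.isnan(b.ic) and not b.flag

    def test_dominant_term_variance_limit(self):
        # N >= 1e6, margins >= 1e3 * a: first variance term dominates
        for a in (3, 125, 1000):
            row = col = 2000 * a
            n = 5_000_000
            v = sg.ic_variance(a, row, col, n)
            dom = sg.ic_variance_dominant(a)
            assert abs(v - dom) <= 0.01 * v


class TestEbgm:
    def test_reference_table(self):
        e = sg.ebgm_stats(REF)
        assert e.ebgm == pytest.approx(9.1818, abs=5e-4)
        assert e.ebgm05 == pytest.approx(5.179, abs=0.01)
        assert e.flag

    def test_proportional_rows_null(self):
        e = sg.ebgm_stats(T(1, 9, 10, 90))
        assert e.ebgm == pytest.approx(1.0)
        assert not e.flag


class TestCrossAlgorithm:
    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    def test_ic_is_log2_ebgm(self, cells):
        t = T(*cells)
        assert sg.bcpnn_stats(t).ic == pytest.approx(math.log2(sg.ebgm_stats(t).ebgm), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(2, 500)] * 4))
    def test_signs_agree(self, cells):
        t = T(*cells)
        s = sg.signal_stats(t)
        signs = {np.sign(s.ic), np.sign(math.log(s.ror)), np.sign(math.log(s.prr))}
        # all three agree whenever none of them is exactly zero
        if 0 not in {round(x, 12) for x in (s.ic, math.log(s.ror), math.log(s.prr))}:
            assert len(signs) == 1

    def test_monotone_in_a(self):
        b, c, d = 50, 40, 4000
        prev = None
        for a in range(1, 30):
            s = sg.signal_stats(T(a, b, c, d))
            cur = (s.ror, s.prr, s.ic, s.ebgm)
            if prev is not None:
                assert all(x > y for x, y in zip(cur, prev))
            prev = cur

    def test_zero_cell_correction(self):
        s = sg.signal_stats(T(5, 95, 0, 900))
        assert s.corrected
        assert math.isfinite(s.ror) and math.isfinite(s.ror_lo)

    def test_cells_must_be_counts(self):
        with pytest.raises(ValueError):
            T(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            T(0, 0, 0, 0)


class TestEventPairs:
    def test_repeated_pt_collapses(self, tiny_tables):
        pairs = sg.event_pairs(tiny_tables["reac"])
        sub = pairs[pairs["primaryid"] == 11]
        assert sorted(sub["term"]) == ["alopecia", "muscle spasms"]

    def test_soc_level_merges_pts(self):
        reac = pd.DataFrame({"primaryid": ["1", "1", "2"], "pt": ["X1", "X2", "X1"]})
        pairs = sg.event_pairs(reac, level="soc", pt_soc={"X1": "S", "X2": "S"})
        # report 1's two PTs of SOC S merge into one pair
        assert len(pairs) == 2
        assert set(pairs["term"]) == {"s"}

    def test_unmapped_pt_warns(self):
        reac = pd.DataFrame({"primaryid": ["1"], "pt": ["Mystery"]})
        with pytest.warns(UserWarning, match="absent from the PT->SOC map"):
            pairs = sg.event_pairs(reac, level="soc", pt_soc={"X1": "S"})
        assert list(pairs["term"]) == ["unclassified"]


class TestContingencyAndTable:
    def make_pairs(self):
        # 10 target reports, 4 with PT "X"; 90 background, 9 with "X";
        # every report carries exactly one PT.
        rows = []
        for i in range(10):
            rows.append((i, "x" if i < 4 else "y"))
        for i in range(10, 100):
            rows.append((i, "x" if i < 19 else "z"))
        return pd.DataFrame(rows, columns=["primaryid", "term"]).assign(
            display=lambda f: f["term"].str.upper()
        )

    def test_planted_fixture_counts(self):
        t = sg.build_contingency(self.make_pairs(), set(range(10)), "X")
        assert (t.a, t.b, t.c, t.d) == (4, 6, 9, 81)

    def test_absent_term_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            t = sg.build_contingency(self.make_pairs(), set(range(10)), "nope")
        assert t.a == t.c == 0

    def test_empty_background(self):
        pairs = self.make_pairs().iloc[:10]
        with pytest.warns(UserWarning, match="empty background"):
            table = sg.signal_table(pairs, set(range(10)))
        assert (~table["positive"]).all()  # undefined stats can never flag

    def test_signal_table_marginals(self):
        pairs = self.make_pairs()
        table = sg.signal_table(pairs, set(range(10)))
        assert (table["a"] + table["b"]).unique().tolist() == [10]
        assert ((table[["a", "b", "c", "d"]].sum(axis=1)) == len(pairs)).all()


class TestScreenAndRank:
    def make_table(self):
        return pd.DataFrame(
            {
                "term": ["x", "y", "z", "w"],
                "display": ["X", "Y", "Z", "W"],
                "a": [12, 3, 100, 9],
                "ebgm": [5.45, 5.45, 106.56, 7.47],
                "positive": [True, True, True, False],
            }
        )

    def test_conjunction_rule(self):
        table = sg.screen_signals(self.make_table())
        assert set(sg.positive_signals(table)["term"]) == {"x", "y", "z"}

    def test_blocklist_reason_recorded(self):
        table = sg.screen_signals(self.make_table(), {"dosing-packaging": ["X"]})
        assert table.loc[table["term"] == "x", "excluded_reason"].item() == "dosing-packaging"
        assert set(sg.positive_signals(table)["term"]) == {"y", "z"}

    def test_rank_by_ebgm_order_and_k(self):
        ranked = sg.rank_by_ebgm(self.make_table(), 2)
        assert list(ranked["ebgm"]) == [106.56, 7.47]

    def test_rank_tie_broken_by_count(self):
        ranked = sg.rank_by_ebgm(self.make_table())
        tied = ranked[ranked["ebgm"] == 5.45]
        assert list(tied["a"]) == [12, 3]

    def test_k_larger_than_table(self):
        assert len(sg.rank_by_ebgm(self.make_table(), 99)) == 4

    def test_report_view_rounds(self, tmp_path):
        table = sg.signal_table(
            pd.DataFrame({"primaryid": [1, 2, 3], "term": list("xxy"),
                          "display": list("XXY")}),
            {1, 2},
        )
        path = sg.write_signal_table(table, tmp_path / "t.tsv", report_view=True)
        assert "\t" in path.read_text()
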