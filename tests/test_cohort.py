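import datetime as dt

import pytest

from faersig import cohort as ch
from faersig.dedup import deduplicate

SYNS = ("ripretinib", "qinlock")


@pytest.fixture
def cases(tiny_tables):
    dd = deduplicate(tiny_tables["demo"])
    matched = ch.match_target_drug(tiny_tables["drug"], SYNS)
    return ch.build_cohort(tiny_tables, dd, matched)


def case_by_pid(cases, pid):
    return next(c for c in cases if c.primaryid == pid)


class TestMatchTargetDrug:
    def test_case_insensitive_substring(self, tiny_tables):
        matched = ch.match_target_drug(tiny_tables["drug"], ("ripretinib",))
        assert (11, 1) in matched  # "RIPRETINIB." with trailing dot

    def test_match_via_prod_ai(self, tiny_tables):
        matched = ch.match_target_drug(tiny_tables["drug"], ("ripretinib",))
        assert (13, 1) in matched  # DRUGNAME "QINLOCK", PROD_AI "ripretinib"

    def test_non_target_not_matched(self, tiny_tables):
        matched = ch.match_target_drug(tiny_tables["drug"], ("ripretinib",))
        assert (14, 2) not in matched  # IMATINIB row
        assert (15, 1) not in matched

    def test_empty_synonyms_error(self, tiny_tables):
        with pytest.raises(ValueError):
            ch.match_target_drug(tiny_tables["drug"], ())


class TestBuildCohort:
    def test_membership(self, cases):
        # kept reports with a PS target row: 21 (supersedes 11), 12, 13.
        # 14 has the target only as concomitant -> excluded; 15 lacks it.
        assert sorted(c.primaryid for c in cases) == [12, 13, 21]

    def test_repeated_pt_counted_once(self, tiny_tables):
        dd = deduplicate(tiny_tables["demo"])
        matched = ch.match_target_drug(tiny_tables["drug"], SYNS)
        # primaryid 11 (pre-dedup revision) lists Alopecia twice
        all_cases = ch.build_cohort(
            tiny_tables,
            deduplicate(tiny_tables["demo"].iloc[[0, 2, 3, 4, 5]].reset_index(drop=True)),
            matched,
        )
        c11 = case_by_pid(all_cases, 11)
        assert [p.lower() for p in c11.pts].count("alopecia") == 1
        assert len(c11.pts) == 2

    def test_indications_restricted_to_target_rows(self, cases):
        c13 = case_by_pid(cases, 13)
        assert c13.indications == ("Gastric cancer",)  # seq-2 Hypertension is IMATINIB's

    def test_therapy_start_earliest_day_precision(self, cases):
        c13 = case_by_pid(cases, 13)
        assert c13.therapy_start == dt.date(2023, 2, 1)
        assert c13.therapy_start_precision == "day"
        c12 = case_by_pid(cases, 12)
        assert c12.therapy_start_precision == "month"

    def test_demographics_parsed(self, cases):
        c21 = case_by_pid(cases, 21)
        assert c21.sex == "M" and c21.age_years == 60.0
        assert c21.report_year == 2023
        assert c21.outcomes == {"HO", "DE"}


class TestSeriousness:
    def make(self, codes):
        return ch.CaseRecord(
            primaryid=1, caseid=1, sex="M", age_years=None, occp_cod="CN",
            reporter_country="US", report_year=2023, event_date=None,
            event_precision=None, outcomes=frozenset(codes),
            target_drug_seqs=frozenset({1}), pts=("Nausea",), indications=(),
            therapy_start=None, therapy_start_precision=None,
        )

    def test_hospitalization_is_serious(self):
        assert ch.classify_seriousness(self.make({"HO"}))

    def test_no_outcomes_non_serious(self):
        assert not ch.classify_seriousness(self.make(set()))

    def test_multiple_codes_single_serious_case(self, cases):
        serious = [c for c in cases if ch.classify_seriousness(c)]
        assert [c.primaryid for c in serious] == [13, 21] or sorted(
            c.primaryid for c in serious
        ) == [13, 21]

    @pytest.mark.parametrize("base", [set(), {"HO"}, {"DE", "LT"}])
    def test_monotone_in_outcome_codes(self, base):
        before = ch.classify_seriousness(self.make(base))
        for extra in ch.SERIOUS_OUTCOME_CODES:
            after = ch.classify_seriousness(self.make(base | {extra}))
            assert after >= before


class TestPercentage:
    def test_half_up_two_decimals(self):
        assert ch.percentage(1, 3) == 33.33
        assert ch.percentage(1, 8) == 12.5
        assert ch.percentage(5, 2000) == 0.25
        assert ch.percentage(1, 0) == 0.0

    def test_rounding_is_half_up_not_bankers(self):
        assert ch.percentage(125, 1000) == 12.5
        assert ch.percentage(1125, 10000) == 11.25
        assert ch.percentage(45, 8000) == 0.56  # 0.5625 -> 0.56; 0.565 would be 0.57


class TestSummary:
    def test_single_male_case(self, cases):
        summary = ch.summarize_cohort(cases[:1])
        gender = dict((cat, (n, p)) for cat, n, p in summary.blocks["gender"])
        assert gender["Female"] == (1, 100.0)  # case 12 is female

    def test_blocks_sum_to_n_cases(self, cases):
        summary = ch.summarize_cohort(cases)
        for block in ("gender", "age", "reporter", "country", "report_year"):
            assert sum(n for _, n, _ in summary.blocks[block]) == summary.n_cases

    def test_outcome_denominator_is_outcome_total(self, cases):
        summary = ch.summarize_cohort(cases)
        out = summary.blocks["outcomes"]
        total = sum(n for _, n, _ in out)
        assert total == 3  # HO, DE (case 21) + OT (case 13)
        assert all(p == ch.percentage(n, total) for _, n, p in out)

    def test_age_band_edges(self):
        assert ch._age_band(65.0) == ">=65"
        assert ch._age_band(64.99) == "18-65"
        assert ch._age_band(17.9) == "<18"
        assert ch._age_band(None) == "Unknown"

    def test_events_counted_at_event_level(self, cases):
        summary = ch.summarize_cohort(cases)
        assert summary.n_events == sum(len(c.pts) for c in cases) == 5

    def test_to_frame_and_write(self, cases, tmp_path):
        summary = ch.summarize_cohort(cases)
        path = ch.write_summary(summary, tmp_path / "t1.tsv")
        text = path.read_text()
        assert "gender\tMale" in text
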