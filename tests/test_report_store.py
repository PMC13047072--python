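from datetime import date

import pytest

from cheilitis_pv.report_store import (
    CurationRules,
    FormatError,
    Sex,
    curate,
    curate_pipeline,
    deduplicate,
    normalize_drug_name,
    parse_flexible_date,
    read_reports,
    write_simple_csv,
)
from cheilitis_pv.synthetic_data import SyntheticConfig, generate

from conftest import make_report


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  isotretinoin ", "ISOTRETINOIN"),
            ("Amoxicillin   Sodium", "AMOXICILLIN"),
            ("METFORMIN HYDROCHLORIDE", "METFORMIN"),
            ("doxycycline  hyclate\t monohydrate", "DOXYCYCLINE HYCLATE MONOHYDRATE"),
        ],
    )
    def test_drug_name(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("20230615", date(2023, 6, 15)),
            ("202306", date(2023, 6, 15)),
            ("2023", date(2023, 7, 1)),
            ("2023-06-15", date(2023, 6, 15)),
            ("UNK", None),
            ("", None),
            ("20231345", None),
            ("garbage", None),
        ],
    )
    def test_flexible_dates(self, raw, expected):
        assert parse_flexible_date(raw) == expected


class TestSimpleCsv:
    def test_rows_aggregate_into_one_report(self, tmp_path):
        p = tmp_path / "in.csv"
        p.write_text(
            "case_id,receipt_date,sex,age_years,weight_kg,reporter,country,"
            "drug_name,drug_role,drug_start_date,event_pt,event_onset_date,outcome_codes\n"
            "c1,2023-01-05,female,44,70,physician,US,ISOTRETINOIN,primary_suspect,"
            "2022-12-01,Cheilitis,2022-12-20,HO;OT\n"
            "c1,2023-01-05,female,44,70,physician,US,DOXYCYCLINE,concomitant,,"
            "Cheilitis,2022-12-20,HO;OT\n"
            "c1,2023-01-05,female,44,70,physician,US,ISOTRETINOIN,primary_suspect,"
            "2022-12-01,Cheilitis,2022-12-20,HO;OT\n"
        )
        (report,) = read_reports([p], dialect="simple_csv")
        assert len(report.drugs) == 2
        assert report.events == ["Cheilitis"]
        assert report.sex is Sex.FEMALE
        assert report.age_years == 44.0
        assert len(report.outcomes) == 2

    def test_unparseable_values_become_missing(self, tmp_path):
        p = tmp_path / "in.csv"
        p.write_text(
            "case_id,receipt_date,sex,age_years,weight_kg,drug_name,event_pt\n"
            "c1,2023-01-05,wat,UNK,-5,DRUGX,Rash\n"
        )
        (report,) = read_reports([p], dialect="simple_csv")
        assert report.age_years is None
        assert report.weight_kg is None
        assert report.sex is Sex.UNKNOWN

    def test_missing_identifier_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("receipt_date,drug_name,event_pt\n2023-01-05,D,E\n")
        with pytest.raises(FormatError, match="case_id"):
            read_reports([p], dialect="simple_csv")

    def test_empty_input_is_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("case_id,drug_name,event_pt\n")
        assert read_reports([p], dialect="simple_csv") == []

    def test_round_trip_is_lossless(self, tmp_path, small_corpus):
        reports, _ = small_corpus
        subset = reports[:300]
        out = tmp_path / "rt.csv"
        write_simple_csv(subset, out)
        back = read_reports([out], dialect="simple_csv")
        assert back == subset


class TestFaersAscii:
    def _write(self, tmp_path):
        (tmp_path / "DEMO24Q1.txt").write_text(
            "primaryid$caseid$caseversion$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country\n"
            "1001$100$1$20240115$20231220$F$45$YR$154$LBS$MD$US\n"
            "1002$101$1$20240116$$M$UNK$YR$$$CN$FR\n"
        )
        (tmp_path / "DRUG24Q1.txt").write_text(
            "primaryid$drug_seq$role_cod$drugname$indi_pt\n"
            "1001$1$PS$Isotretinoin$Acne\n"
            "1001$2$C$doxycycline$\n"
            "1002$1$PS$AMOXICILLIN$\n"
        )
        (tmp_path / "REAC24Q1.txt").write_text(
            "primaryid$pt\n1001$Cheilitis\n1001$Dry skin\n1002$Rash\n"
        )
        (tmp_path / "OUTC24Q1.txt").write_text("primaryid$outc_cod\n1001$HO\n")
        (tmp_path / "THER24Q1.txt").write_text(
            "primaryid$dsg_drug_seq$start_dt\n1001$1$20231201\n"
        )

    def test_tables_join_on_primaryid(self, tmp_path):
        self._write(tmp_path)
        reports = read_reports(tmp_path, dialect="faers_ascii")
        assert len(reports) == 2
        r1 = next(r for r in reports if r.case_id == "100")
        assert {d.name for d in r1.drugs} == {"ISOTRETINOIN", "DOXYCYCLINE"}
        assert r1.events == ["Cheilitis", "Dry skin"]
        assert r1.weight_kg == pytest.approx(154 * 0.45359237)
        assert r1.drugs[0].start_date == date(2023, 12, 1)
        assert r1.drugs[0].indication == "Acne"

    def test_unk_age_becomes_missing(self, tmp_path):
        self._write(tmp_path)
        reports = read_reports(tmp_path, dialect="faers_ascii")
        r2 = next(r for r in reports if r.case_id == "101")
        assert r2.age_years is None
        assert r2.weight_kg is None

    def test_missing_primaryid_is_format_error(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("caseid$sex\n1$F\n")
        with pytest.raises(FormatError, match="primaryid"):
            read_reports(tmp_path, dialect="faers_ascii")


class TestDeduplicate:
    def test_latest_receipt_wins(self):
        old = make_report("c1", receipt=date(2023, 1, 1))
        new = make_report("c1", receipt=date(2023, 6, 1), events=("Rash",))
        kept, log = deduplicate([old, new])
        assert kept == [new]
        assert (log.n_raw, log.n_after_dedup) == (2, 1)

    def test_version_breaks_receipt_ties(self):
        v1 = make_report("c1", version=1)
        v2 = make_report("c1", version=2, events=("Rash",))
        kept, _ = deduplicate([v2, v1])
        assert kept == [v2]

    def test_distinct_ids_identity(self):
        reports = [make_report(f"c{i}") for i in range(5)]
        kept, _ = deduplicate(reports)
        assert kept == reports

    def test_idempotent(self):
        reports = [make_report("c1", version=1), make_report("c1", version=3),
                   make_report("c2")]
        once, _ = deduplicate(reports)
        twice, _ = deduplicate(once)
        assert once == twice

    def test_order_insensitive_up_to_tiebreak(self):
        a = make_report("c1", receipt=date(2023, 1, 1))
        b = make_report("c1", receipt=date(2023, 6, 1))
        c = make_report("c2")
        kept_fwd, _ = deduplicate([a, b, c])
        kept_rev, _ = deduplicate([c, b, a])
        assert set(r.case_id for r in kept_fwd) == set(r.case_id for r in kept_rev)
        assert {r.receipt_date for r in kept_fwd if r.case_id == "c1"} == {date(2023, 6, 1)}


class TestCurate:
    def test_cohort_and_background_counts(self):
        reports = [
            make_report(f"c{i}", events=("Cheilitis",) if i < 4 else ("Rash",))
            for i in range(10)
        ]
        cohort, background, log = curate(reports, "cheilitis")
        assert len(cohort) == 4
        assert len(background) == 10
        assert log.n_final == 10

    def test_drugless_report_excluded(self):
        good = make_report("c1")
        bad = make_report("c2")
        bad.drugs = []
        cohort, background, log = curate([good, bad], "Cheilitis")
        assert log.n_excluded_nondrug == 1
        assert len(background) == 1

    def test_eventless_report_counts_as_incomplete(self):
        bad = make_report("c1")
        bad.events = []
        _, background, log = curate([bad], "Cheilitis")
        assert log.n_excluded_incomplete == 1
        assert background == []

    def test_year_window_exclusion(self):
        old = make_report("c1", receipt=date(1999, 1, 1))
        _, background, log = curate([old], "Cheilitis",
                                    CurationRules(year_min=2004, year_max=2025))
        assert background == []
        assert log.n_excluded_incomplete == 1

    def test_empty_target_event_rejected(self):
        with pytest.raises(ValueError):
            curate([make_report("c1")], "  ")

    def test_report_conservation(self, small_corpus):
        reports, _ = small_corpus
        cohort, background, log = curate_pipeline(reports, "Cheilitis")
        assert log.n_after_dedup == (
            log.n_final + log.n_excluded_nondrug + log.n_excluded_incomplete
        )
        assert set(r.case_id for r in cohort) <= set(r.case_id for r in background)

    def test_matching_is_exact_not_substring(self):
        r = make_report("c1", events=("Cheilitis angular",))
        cohort, _, _ = curate([r], "Cheilitis")
        assert cohort == []
        cohort, _, _ = curate(
            [r], "Cheilitis", CurationRules(synonyms=("Cheilitis angular",))
        )
        assert cohort == [r]


def test_generator_cohort_size_matches_truth(small_corpus):
    reports, truth = small_corpus
    cohort, _, _ = curate_pipeline(reports, "Cheilitis")
    with_event = sum(1 for r in reports if "cheilitis" in r.event_terms())
    assert len(cohort) == with_event
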