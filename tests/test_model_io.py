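"""Report model, flat-CSV/FAERS readers, deduplication and selection."""

from datetime import date

import pytest

from pvscreen import (
    ConfigError,
    FormatError,
    SynonymTable,
    deduplicate,
    normalize_drug_name,
    read_reports,
    select_drug_reports,
    write_reports,
)
from pvscreen.io import parse_date
from pvscreen.model import ReportStore
from pvscreen.synthetic import SyntheticConfig, generate

from conftest import make_report


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Ublituximab ", "ublituximab"),
            ("BRIUMVI (ublituximab)", "briumvi ublituximab"),
            ("aspirin-100mg.", "aspirin 100mg"),
        ],
    )
    def test_drug_name_normalization(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_synonym_table_maps_brand_to_generic(self):
        syn = SynonymTable({"BRIUMVI": "ublituximab"})
        assert syn.resolve("briumvi.") == "ublituximab"
        assert syn.resolve("Ublituximab") == "ublituximab"
        assert syn.resolve("unrelated") == "unrelated"


class TestDateParsing:
    @pytest.mark.parametrize(
        "raw,expected,imprecise",
        [
            ("2024-03-15", date(2024, 3, 15), False),
            ("20240315", date(2024, 3, 15), False),
            ("202403", date(2024, 3, 1), True),
            ("2024", date(2024, 1, 1), True),
            (None, None, False),
        ],
    )
    def test_iso_and_faers_partial_dates(self, raw, expected, imprecise):
        got, got_imprecise = parse_date(raw)
        assert got == expected
        assert got_imprecise == imprecise

    def test_unparseable_date_warns_and_is_unknown(self):
        with pytest.warns(UserWarning, match="unparseable"):
            got, _ = parse_date("not-a-date", "R9")
        assert got is None


class TestFlatCsvReader:
    def test_rows_sharing_report_id_group_into_one_report(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "report_id,case_version,receipt_date,sex,age_years,age_unit,region,"
            "serious,drug_name,drug_role,therapy_start,pt,onset_date,outcome\n"
            "R1,1,2024-01-01,female,33,yr,americas,0,drugA,suspect,,headache,,unknown\n"
            "R1,1,2024-01-01,female,33,yr,americas,0,drugB,concomitant,,headache,,unknown\n"
            "R1,1,2024-01-01,female,33,yr,americas,0,drugA,suspect,,headache,,unknown\n"
        )
        store = read_reports(path)
        assert len(store) == 1
        (report,) = store.reports
        assert len(report.drugs) == 2
        assert len(report.reactions) == 1
        assert report.sex == "female" and report.age_years == 33

    def test_header_only_file_gives_empty_store(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "report_id,case_version,receipt_date,sex,age_years,age_unit,region,"
            "serious,drug_name,drug_role,therapy_start,pt,onset_date,outcome\n"
        )
        assert len(read_reports(path)) == 0

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("report_id,drug_name\nR1,drugA\n")
        with pytest.raises(FormatError, match="pt"):
            read_reports(path)

    def test_age_unit_conversion_months_and_decades(self, tmp_path):
        path = tmp_path / "ages.csv"
        path.write_text(
            "report_id,drug_name,pt,age_years,age_unit\n"
            "R1,drugA,headache,24,mon\n"
            "R2,drugA,headache,6,dec\n"
        )
        store = read_reports(path)
        by_id = {r.report_id: r for r in store}
        assert by_id["R1"].age_years == pytest.approx(2.0)
        assert by_id["R2"].age_years == pytest.approx(60.0)

    def test_missing_demographics_become_unknown_not_dropped(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("report_id,drug_name,pt\nR1,drugA,headache\n")
        store = read_reports(path)
        assert len(store) == 1
        assert store.reports[0].sex == "unknown"
        assert store.reports[0].age_years is None

    def test_round_trip_on_synthetic_store(self, tmp_path):
        cfg = SyntheticConfig(seed=7, n_background_records=1500, n_target_reports=100)
        store, _ = generate(cfg)
        path = tmp_path / "rt.csv"
        write_reports(store, path)
        back = read_reports(path)
        assert len(back) == len(store)
        orig = {r.report_id: r for r in store}
        for r in back.reports:
            o = orig[r.report_id]
            assert r.sex == o.sex and r.region == o.region and r.serious == o.serious
            assert (r.age_years is None) == (o.age_years is None)
            if r.age_years is not None:
                assert r.age_years == pytest.approx(o.age_years)
            assert {(d.drug_name, d.role, d.therapy_start) for d in r.drugs} == {
                (d.drug_name, d.role, d.therapy_start) for d in o.drugs
            }
            assert {(x.pt, x.onset_date) for x in r.reactions} == {
                (x.pt, x.onset_date) for x in o.reactions
            }


class TestFaersAsciiReader:
    def test_dollar_delimited_tables_join_on_primaryid(self, tmp_path):
        (tmp_path / "DEMO24Q1.txt").write_text(
            "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod\n"
            "100$C100$2$20240215$F$45$YR\n"
            "200$C200$1$202401$M$360$MON\n"
        )
        (tmp_path / "DRUG24Q1.txt").write_text(
            "primaryid$drugname$role_cod\n100$DrugA$PS\n100$DrugB$C\n200$DrugA$SS\n"
        )
        (tmp_path / "REAC24Q1.txt").write_text(
            "primaryid$pt\n100$Headache\n100$Nausea\n200$Rash\n"
        )
        (tmp_path / "THER24Q1.txt").write_text(
            "primaryid$start_dt\n100$20240101\n"
        )
        store = read_reports(tmp_path, dialect="faers_ascii")
        by_id = {r.report_id: r for r in store}
        assert set(by_id) == {"C100", "C200"}
        r = by_id["C100"]
        assert r.case_version == 2 and r.sex == "female"
        assert {d.role for d in r.drugs} == {"suspect", "concomitant"}
        assert r.drugs[0].therapy_start == date(2024, 1, 1)
        assert by_id["C200"].age_years == pytest.approx(30.0)
        assert by_id["C200"].receipt_date == date(2024, 1, 1)


class TestDeduplicate:
    def test_highest_case_version_wins(self):
        store = ReportStore(
            [
                make_report("R1", ["a"], ["headache"], version=1),
                make_report("R1", ["a"], ["headache", "rash"], version=2),
            ]
        )
        out = deduplicate(store)
        assert len(out) == 1
        assert out.reports[0].case_version == 2

    def test_version_tie_broken_by_latest_receipt(self):
        store = ReportStore(
            [
                make_report("R1", ["a"], ["headache"], receipt=date(2024, 1, 1)),
                make_report("R1", ["a"], ["rash"], receipt=date(2024, 5, 1)),
            ]
        )
        out = deduplicate(store)
        assert out.reports[0].reactions[0].pt == "rash"

    def test_identical_content_collapses_to_smallest_id(self):
        r1 = make_report("R2", ["a"], ["headache"], sex="female", age=30)
        r2 = make_report("R1", ["a"], ["headache"], sex="female", age=30)
        out = deduplicate(ReportStore([r1, r2]))
        assert [r.report_id for r in out] == ["R1"]

    def test_idempotent_and_never_grows(self, mixed_store):
        once = deduplicate(mixed_store)
        twice = deduplicate(once)
        assert len(once) <= len(mixed_store)
        assert [r.report_id for r in twice] == [r.report_id for r in once]


class TestSelectDrugReports:
    def test_filters_by_name_and_role(self, mixed_store):
        suspects = select_drug_reports(mixed_store, "targetol", roles={"suspect"})
        assert len(suspects) == 4
        conc = select_drug_reports(mixed_store, "adjuvin", roles={"suspect"})
        assert {r.report_id for r in conc} == {"M08", "M10"}

    def test_role_superset_gives_report_superset(self, mixed_store):
        small = {r.report_id for r in select_drug_reports(mixed_store, "adjuvin", roles={"suspect"})}
        big = {r.report_id for r in select_drug_reports(mixed_store, "adjuvin", roles={"suspect", "concomitant"})}
        assert small <= big
        assert "M03" in big - small

    def test_brand_name_matches_through_synonyms(self, mixed_store):
        syn = SynonymTable({"Targetomab": "targetol"})
        got = select_drug_reports(mixed_store, "TARGETOMAB", synonyms=syn)
        assert len(got) == 4

    def test_empty_drug_rejected(self, mixed_store):
        with pytest.raises(ConfigError):
            select_drug_reports(mixed_store, "")

    def test_generator_manifest_count_matches_selection(self):
        cfg = SyntheticConfig(seed=3, n_background_records=4000, n_target_reports=250)
        store, manifest = generate(cfg)
        deduped = deduplicate(store)
        selected = select_drug_reports(deduped, cfg.target_drug)
        assert len(selected) == manifest.n_target_reports
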