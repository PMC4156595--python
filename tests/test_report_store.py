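import logging

import numpy as np
import pytest

from pvsignal import (
    FileDialect,
    Gender,
    PartialDate,
    ReportDatabase,
    SafetyReport,
    normalize_drug_name,
    read_reports,
    write_reports,
)
from pvsignal.report_store import DEFAULT_SALT_SUFFIXES, SchemaError

from conftest import make_report, random_small_db


@pytest.mark.parametrize(
    "text,expected",
    [
        ("20120827", PartialDate(2012, 8, 27)),
        ("201208", PartialDate(2012, 8)),
        ("2012", PartialDate(2012)),
        ("20120000", PartialDate(2012)),
        ("20120800", PartialDate(2012, 8)),
        ("", None),
    ],
)
def test_partial_date_parse(text, expected):
    assert PartialDate.parse(text) == expected


def test_partial_date_roundtrip_and_order():
    d = PartialDate(2012, 8, 27)
    assert PartialDate.parse(d.encode()) == d
    assert PartialDate(2010).sort_key() < PartialDate(2010, 1, 1).sort_key()
    with pytest.raises(ValueError):
        PartialDate.parse("2012-08-27")
    with pytest.raises(ValueError):
        PartialDate(2012, day=5)


@pytest.mark.parametrize(
    "raw,kwargs,expected",
    [
        ("EFAVIRENZ ", {}, ["efavirenz"]),
        (
            "Efavirenz/Emtricitabine/Tenofovir  Disoproxil Fumarate",
            {},
            ["efavirenz", "emtricitabine", "tenofovir disoproxil fumarate"],
        ),
        (
            "ATRIPLA",
            {},
            ["efavirenz", "emtricitabine", "tenofovir disoproxil fumarate"],
        ),
        (
            "Atazanavir Sulfate",
            {"salt_suffixes": DEFAULT_SALT_SUFFIXES},
            ["atazanavir"],
        ),
        # salt stripping is off unless configured
        ("Atazanavir Sulfate", {}, ["atazanavir sulfate"]),
        # ester names that are part of the active moiety survive stripping
        (
            "Tenofovir Disoproxil Fumarate",
            {"salt_suffixes": DEFAULT_SALT_SUFFIXES},
            ["tenofovir disoproxil fumarate"],
        ),
    ],
)
def test_normalize_drug_name(raw, kwargs, expected):
    assert normalize_drug_name(raw, **kwargs) == expected


def test_normalize_rejects_empty_names():
    with pytest.raises(ValueError):
        normalize_drug_name("   ")


def test_report_collapses_duplicate_drugs_and_events():
    r = make_report("r1", drugs=["a", "a"], events=["x", "X "])
    assert len(r.drugs) == 1
    assert len(r.events) == 1
    assert r.event_terms == {"x"}


def test_report_age_validation():
    with pytest.raises(ValueError):
        make_report("r1", age=151.0)


def _write_fixture_files(tmp_path, demo_rows, drug_rows, reac_rows):
    demo = tmp_path / "demo.txt"
    drug = tmp_path / "drug.txt"
    reac = tmp_path / "reac.txt"
    demo.write_text(
        "primaryid$source$sex$age$death_dt$receipt_dt$mfr_sndr\n"
        + "".join(r + "\n" for r in demo_rows)
    )
    drug.write_text(
        "primaryid$drugname$role_cod$start_dt\n" + "".join(r + "\n" for r in drug_rows)
    )
    reac.write_text(
        "primaryid$pt$onset_dt\n" + "".join(r + "\n" for r in reac_rows)
    )
    return demo, drug, reac


def test_read_reports_joins_three_tables(tmp_path):
    demo, drug, reac = _write_fixture_files(
        tmp_path,
        ["1$spontaneous$F$34$$20120101$ACME", "2$study$M$55.5$20110301$20110401$OTHER"],
        ["1$EFAVIRENZ$PS$20100101", "1$Nevirapine$C$", "2$raltegravir$PS$2009"],
        ["1$Suicidal Ideation$20100201", "1$suicide attempt$", "2$myopathy$201003"],
    )
    db = read_reports(demo, drug, reac)
    assert len(db) == 2
    r1 = db["1"]
    assert r1.gender is Gender.F and r1.age_years == 34
    assert r1.drug_names == {"efavirenz", "nevirapine"}
    assert r1.event_terms == {"suicidal ideation", "suicide attempt"}
    assert db["2"].drug_names == {"raltegravir"}
    assert db.reports_with_drug("efavirenz") == {"1"}
    assert db.reports_with_pt("Suicidal Ideation") == {"1"}


def test_orphan_drug_row_creates_report_with_missing_demographics(tmp_path):
    demo, drug, reac = _write_fixture_files(
        tmp_path,
        ["1$spontaneous$F$34$$$ACME"],
        ["1$efavirenz$PS$", "99$atazanavir$PS$"],
        ["1$headache$"],
    )
    db = read_reports(demo, drug, reac)
    assert len(db) == 2
    orphan = db["99"]
    assert orphan.gender is Gender.UNKNOWN
    assert orphan.age_years is None
    assert orphan.drug_names == {"atazanavir"}


def test_repeated_pt_rows_collapse_to_one_event(tmp_path):
    demo, drug, reac = _write_fixture_files(
        tmp_path,
        ["1$spontaneous$F$34$$$ACME"],
        ["1$efavirenz$PS$"],
        ["1$suicidal ideation$", "1$SUICIDAL IDEATION$20100101"],
    )
    db = read_reports(demo, drug, reac)
    assert len(db["1"].events) == 1


def test_malformed_rows_are_skipped_and_counted(tmp_path, caplog):
    demo, drug, reac = _write_fixture_files(
        tmp_path,
        ["1$spontaneous$F$34$$$ACME", "$spontaneous$M$40$$$X", "short$row"],
        ["1$efavirenz$PS$"],
        ["1$headache$"],
    )
    with caplog.at_level(logging.INFO, logger="pvsignal.report_store"):
        db = read_reports(demo, drug, reac)
    assert len(db) == 1
    assert any("skipped malformed: 2/0/0" in m for m in caplog.messages)


def test_missing_id_column_raises_schema_error(tmp_path):
    demo = tmp_path / "demo.txt"
    demo.write_text("not_the_id$sex\n1$F\n")
    drug = tmp_path / "drug.txt"
    drug.write_text("primaryid$drugname$role_cod$start_dt\n")
    reac = tmp_path / "reac.txt"
    reac.write_text("primaryid$pt$onset_dt\n")
    with pytest.raises(SchemaError):
        read_reports(demo, drug, reac)


def test_unreadable_source_raises_io_error_naming_file(tmp_path):
    with pytest.raises(OSError, match="demo"):
        read_reports(tmp_path / "demo_missing.txt", tmp_path / "d", tmp_path / "r")


def test_roundtrip_identity_on_canonical_database(tmp_path):
    rng = np.random.default_rng(42)
    db = random_small_db(rng, 25)
    paths = (tmp_path / "demo.txt", tmp_path / "drug.txt", tmp_path / "reac.txt")
    write_reports(db, *paths)
    db2 = read_reports(*paths)
    # canonicalize once, then the round trip is exact
    write_reports(db2, *paths)
    assert read_reports(*paths) == db2
    assert {r.report_id for r in db2} == {r.report_id for r in db}


def test_roundtrip_preserves_missing_ages(tmp_path):
    db = ReportDatabase(
        [
            make_report("r1", age=None, drugs=["a"], events=["x"]),
            make_report("r2", age=33.5, drugs=["b"], events=["y"]),
        ]
    )
    paths = (tmp_path / "demo.txt", tmp_path / "drug.txt", tmp_path / "reac.txt")
    write_reports(db, *paths)
    db2 = read_reports(*paths)
    assert db2["r1"].age_years is None
    assert db2["r2"].age_years == 33.5


def test_empty_database_writes_header_only_files(tmp_path):
    paths = (tmp_path / "demo.txt", tmp_path / "drug.txt", tmp_path / "reac.txt")
    write_reports(ReportDatabase(), *paths)
    for p in paths:
        assert len(p.read_text().strip().splitlines()) == 1
    assert len(read_reports(*paths)) == 0


def test_duplicate_report_ids_rejected():
    with pytest.raises(ValueError):
        ReportDatabase([make_report("r1"), make_report("r1")])


def test_index_consistency_under_rebuild():
    rng = np.random.default_rng(7)
    db = random_small_db(rng, 40)
    db.check_invariants()
    for drug, ids in db.drug_index.items():
        assert ids == {r.report_id for r in db if drug in r.drug_names}
    for pt, ids in db.pt_index.items():
        assert ids == {r.report_id for r in db if pt in r.event_terms}
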