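"""Schema-validated CSV I/O and cross-table consistency checks."""

import numpy as np
import pandas as pd
import pytest

import dendroclean as dc
from dendroclean.data_model import (SCHEMAS, SchemaError, ValidationError,
                                    decimal_year, read_table, validate_dataset,
                                    write_table)


def test_round_trip_is_identity_on_all_generated_tables(small_stand,
                                                        tmp_path):
    _, _, tables = small_stand
    for name, df in tables.items():
        p = tmp_path / f"{name}.csv"
        write_table(df, name, p)
        back = read_table(p, name)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)
        # second write is bit-identical
        first = p.read_bytes()
        write_table(back, name, p)
        assert p.read_bytes() == first


def test_empty_record_set_writes_header_only(tmp_path):
    p = tmp_path / "area.csv"
    write_table(pd.DataFrame(columns=SCHEMAS["area"].column_names), "area", p)
    assert p.read_text() == "plot,area\n"
    assert len(read_table(p, "area")) == 0


def test_out_of_domain_species_rejected(tmp_path):
    p = tmp_path / "pos.csv"
    header = ",".join(SCHEMAS["pos"].column_names)
    row = "1,1,0.0,0.0,400,ABAL,TRUE,1888,TRUE,,,16.0,48.0"
    p.write_text(f"{header}\n{row}\n")
    with pytest.raises(ValidationError, match="species"):
        read_table(p, "pos")


def test_removal_code_9_accepted_with_remove_date(tmp_path):
    p = tmp_path / "pos.csv"
    header = ",".join(SCHEMAS["pos"].column_names)
    row = "1,1,0.0,0.0,400,PCAB,TRUE,1888,TRUE,1950-10-01,9,16.0,48.0"
    p.write_text(f"{header}\n{row}\n")
    df = read_table(p, "pos")
    assert df.loc[0, "removeal"] == 9
    assert df.loc[0, "removeDate"] == pd.Timestamp("1950-10-01")


def test_removal_reason_without_date_rejected(tmp_path):
    p = tmp_path / "pos.csv"
    header = ",".join(SCHEMAS["pos"].column_names)
    row = "1,1,0.0,0.0,400,PCAB,TRUE,1888,TRUE,,9,16.0,48.0"
    p.write_text(f"{header}\n{row}\n")
    with pytest.raises(ValidationError, match="removeal"):
        read_table(p, "pos")


def test_unknown_column_is_a_schema_error(tmp_path):
    p = tmp_path / "area.csv"
    p.write_text("plot,surface\n1,100\n")
    with pytest.raises(SchemaError):
        read_table(p, "area")


def test_unparseable_date_rejected(tmp_path):
    p = tmp_path / "date.csv"
    p.write_text("plot,year,obs,date\n1,1923,1,23-10-01\n")
    with pytest.raises(ValidationError, match="date"):
        read_table(p, "date")


def test_zero_is_a_value_not_absent(tmp_path):
    p = tmp_path / "dbhObs.csv"
    header = ",".join(SCHEMAS["dbhObs"].column_names)
    # crown code 0 = "normal" must survive a round trip as 0, not NA
    row = "1,1,1923,1,100,,,,,,,,,0,,"
    p.write_text(f"{header}\n{row}\n")
    df = read_table(p, "dbhObs")
    assert df.loc[0, "crown"] == 0
    assert pd.isna(df.loc[0, "stem"])
    assert pd.isna(df.loc[0, "dbh2"])


def test_write_refuses_crown_base_above_height(tmp_path):
    df = pd.DataFrame({"plot": [1], "tree": [1], "year": [1990], "obs": [1],
                       "d": [200.0], "h": [150.0], "hCr": [160.0]})
    with pytest.raises(ValidationError, match="hCr"):
        write_table(df, "dhcComplSmooth", tmp_path / "out.csv")


def test_consistent_synthetic_dataset_yields_empty_report(small_stand):
    _, _, tables = small_stand
    assert validate_dataset(tables) == []


def test_referential_break_reported(small_stand):
    _, _, tables = small_stand
    broken = dict(tables)
    bad = tables["dbhObs"].copy()
    bad.loc[bad.index[0], "tree"] = 99999
    broken["dbhObs"] = bad
    issues = validate_dataset(broken)
    assert any(i.kind == "referential" and i.table == "dbhObs"
               for i in issues)


def test_observation_after_removal_reported(small_stand):
    _, _, tables = small_stand
    pos = tables["pos"].copy()
    obs = tables["dbhObs"]
    # force one observed tree's removal date before its first observation
    target = obs.iloc[0]
    sel = (pos["plot"] == target["plot"]) & (pos["tree"] == target["tree"])
    pos.loc[sel, "removeDate"] = pd.Timestamp("1900-01-01")
    pos.loc[sel, "removeal"] = 1
    issues = validate_dataset({**tables, "pos": pos})
    assert any(i.kind == "temporal" for i in issues)


def test_decimal_year_examples():
    assert decimal_year("1950-01-01") == pytest.approx(1950 + 1 / 365.25)
    mid = decimal_year("1950-07-02")
    assert 1950.49 < mid < 1950.51
    assert decimal_year("1951-01-01") > decimal_year("1950-12-31")


def test_dataset_round_trip_through_directory(small_stand, tmp_path):
    _, _, tables = small_stand
    dc.write_dataset(tables, tmp_path)
    back = dc.read_dataset(tmp_path)
    assert set(back) == set(tables)
    for name in tables:
        pd.testing.assert_frame_equal(back[name], tables[name],
                                      check_dtype=False)
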