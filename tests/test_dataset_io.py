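"""CSV schema readers/writers/validators: round trips, dialects, fault injection."""

import numpy as np
import pandas as pd
import pytest

from nppu import (
    SCHEMAS,
    SchemaError,
    frame_to_records,
    generate_species,
    read_species_records,
    read_table,
    records_to_frame,
    validate_table,
    write_table,
)
from nppu.cli import compute_fresh_frame


@pytest.fixture
def marine_frame():
    records = generate_species()
    return compute_fresh_frame(records[:4], "marine", "T3")


def test_every_nppu_schema_pairs_g_and_kg_columns():
    """Each fresh/milk/SD schema carries the NPPU value in both units."""
    for sid in ("plant", "marine_fresh", "freshwater_fresh",
                "other_animal_fresh", "milk", "nppu_sd"):
        headers = [c.header for c in SCHEMAS[sid].columns]
        assert "NPPU_g/kg" in headers and "NPPU_kg/kg" in headers


def test_unknown_schema_rejected(tmp_path):
    with pytest.raises(SchemaError, match="unknown schema"):
        read_table(tmp_path / "x.csv", "not_a_schema")


def test_round_trip_identity(tmp_path, marine_frame):
    """write then read returns value-identical data (tolerance 1e-9)."""
    path = tmp_path / "marine.csv"
    write_table(marine_frame, path, "marine_fresh")
    back = read_table(path, "marine_fresh")
    assert list(back.columns) == list(marine_frame.columns)
    for col in marine_frame.columns:
        a, b = marine_frame[col], back[col]
        if pd.api.types.is_numeric_dtype(marine_frame[col]):
            np.testing.assert_allclose(
                a.to_numpy(float), b.to_numpy(float), rtol=1e-9, atol=1e-12
            )
        else:
            assert (a.fillna("").astype(str) == b.fillna("").astype(str)).all()


def test_round_trip_records(tmp_path):
    records = generate_species()[:3]
    path = tmp_path / "fresh.csv"
    write_table(records_to_frame(records, "marine_fresh"), path, "marine_fresh")
    back = read_species_records(path, "marine_fresh")
    for orig, re_read in zip(records, back):
        assert re_read.species == orig.species
        assert re_read.trophic.TL == pytest.approx(orig.trophic.TL, rel=1e-9)
        assert re_read.trophic.TE == pytest.approx(orig.trophic.TE, rel=1e-9)
        assert re_read.composition.protein == pytest.approx(
            orig.composition.protein, rel=1e-9
        )


def test_header_only_file_gives_empty_table(tmp_path):
    path = tmp_path / "empty.csv"
    headers = ",".join(c.header for c in SCHEMAS["marine_fresh"].columns)
    path.write_text(headers + "\n", encoding="utf-8")
    frame = read_table(path, "marine_fresh")
    assert len(frame) == 0
    assert frame_to_records(frame, "marine_fresh") == []


def test_empty_record_list_writes_header_only(tmp_path):
    path = tmp_path / "empty_out.csv"
    write_table(records_to_frame([], "marine_fresh"), path, "marine_fresh")
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    assert len(lines) == 1
    assert lines[0].split(",")[0] == "Specie"


def test_missing_required_column_named_in_error(tmp_path):
    path = tmp_path / "broken.csv"
    path.write_text("Common_name,Trophic_level\nfishy,3.0\n", encoding="utf-8")
    with pytest.raises(SchemaError, match="Specie"):
        read_table(path, "marine_fresh")


def test_unparseable_cell_reports_row(tmp_path):
    path = tmp_path / "badnum.csv"
    path.write_text(
        "Specie,Trophic_level\nGood fish,3.0\nBad fish,not-a-number\n",
        encoding="utf-8",
    )
    with pytest.raises(SchemaError, match="row 1"):
        read_table(path, "marine_fresh")


def test_percent_dialect_te_normalized(tmp_path):
    """A Transfer_efficiency of '10' (percent dialect) reads as fraction 0.10."""
    path = tmp_path / "te.csv"
    path.write_text(
        "Specie,Trophic_level,Transfer_efficiency\na,3.0,10\nb,3.0,0.119\n",
        encoding="utf-8",
    )
    frame = read_table(path, "marine_fresh")
    assert frame["transfer_efficiency"].tolist() == pytest.approx([0.10, 0.119])


def test_semicolon_comma_dialect_sniffed(tmp_path):
    """French-dialect files (semicolon delimiter, comma decimals) parse identically."""
    path = tmp_path / "fr.csv"
    path.write_text(
        "Specie;Trophic_level;Protein_%\nSardina synthetica;3,2;17,5\n",
        encoding="utf-8",
    )
    frame = read_table(path, "marine_fresh")
    assert frame.loc[0, "trophic_level"] == pytest.approx(3.2)
    assert frame.loc[0, "protein"] == pytest.approx(175.0)  # percent -> g/kg


def test_composition_percent_scaling_round_trip(tmp_path, marine_frame):
    path = tmp_path / "pct.csv"
    write_table(marine_frame, path, "marine_fresh")
    on_disk = pd.read_csv(path)
    # g/kg internally, percent on disk
    np.testing.assert_allclose(
        on_disk["Protein_%"].to_numpy(), marine_frame["protein"].to_numpy() / 10.0,
        rtol=1e-12,
    )
    np.testing.assert_allclose(
        on_disk["Transfer_efficiency"].to_numpy(),
        marine_frame["transfer_efficiency"].to_numpy() * 100.0,
        rtol=1e-12,
    )


def test_writer_enforces_unit_pair_consistency(tmp_path, marine_frame):
    """The emitted kg/kg column is re-derived from g/kg even if inconsistent."""
    tampered = marine_frame.copy()
    tampered["nppu_kg"] = tampered["nppu_g"]  # wildly wrong
    path = tmp_path / "fixed.csv"
    write_table(tampered, path, "marine_fresh")
    on_disk = pd.read_csv(path)
    np.testing.assert_allclose(
        on_disk["NPPU_kg/kg"].to_numpy(), on_disk["NPPU_g/kg"].to_numpy() / 1000.0,
        rtol=1e-12,
    )


def test_writer_refuses_missing_required_field(tmp_path, marine_frame):
    no_species = marine_frame.drop(columns=["species"])
    path = tmp_path / "never.csv"
    with pytest.raises(SchemaError, match="Specie"):
        write_table(no_species, path, "marine_fresh")
    assert not path.exists()  # nothing written


class TestValidation:
    def test_well_formed_table_passes(self, tmp_path, marine_frame):
        path = tmp_path / "good.csv"
        write_table(marine_frame, path, "marine_fresh")
        report = validate_table(path, "marine_fresh")
        assert report.passed
        assert report.n_rows == len(marine_frame)
        assert "PASS" in report.summary()

    def test_nppu_unit_mismatch_flagged_at_row(self, tmp_path, marine_frame):
        path = tmp_path / "bad_pair.csv"
        write_table(marine_frame, path, "marine_fresh")
        disk = pd.read_csv(path)
        disk.loc[2, "NPPU_kg/kg"] = disk.loc[2, "NPPU_g/kg"]  # off by x1000
        disk.to_csv(path, index=False)
        report = validate_table(path, "marine_fresh")
        errors = [f for f in report.findings if f.severity == "error"]
        assert len(errors) == 1
        assert errors[0].rule == "nppu_unit_consistency"
        assert errors[0].row == 2

    def test_trophic_level_below_one_flagged(self, tmp_path):
        path = tmp_path / "low_tl.csv"
        path.write_text("Specie,Trophic_level\nweird,0.5\n", encoding="utf-8")
        report = validate_table(path, "marine_fresh")
        assert not report.passed
        assert any(f.rule == "tl_minimum" and f.row == 0 for f in report.findings)

    def test_te_out_of_range_flagged(self, tmp_path):
        path = tmp_path / "bad_te.csv"
        # 150 -> percent dialect -> 1.5 as a fraction: out of (0, 1]
        path.write_text(
            "Specie,Trophic_level,Transfer_efficiency\nx,3.0,150\n", encoding="utf-8"
        )
        report = validate_table(path, "marine_fresh")
        assert any(f.rule == "te_range" for f in report.findings)

    def test_composition_oversum_flagged(self, tmp_path):
        path = tmp_path / "oversum.csv"
        path.write_text(
            "Specie,Trophic_level,Moisture_%,Protein_%,Fat_%,Ash_%,Carbohydrates_%\n"
            "x,3.0,70,30,10,5,2\n",  # sums to 117 %
            encoding="utf-8",
        )
        report = validate_table(path, "marine_fresh")
        assert any(f.rule == "composition_closure" for f in report.findings)

    def test_negative_sd_flagged(self, tmp_path):
        path = tmp_path / "neg_sd.csv"
        path.write_text(
            "Specie,NPPU_g/kg,NPPU_kg/kg,NPPU_SD_g/kg\nx,100,0.1,-3\n",
            encoding="utf-8",
        )
        report = validate_table(path, "nppu_sd")
        assert any(f.rule == "sd_nonnegative" for f in report.findings)

    def test_unparseable_cells_are_findings_not_exceptions(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_text("Specie,Trophic_level\nx,abc\n", encoding="utf-8")
        report = validate_table(path, "marine_fresh")
        assert not report.passed
        assert any(f.rule == "unparseable_cell" for f in report.findings)

    def test_missing_file_is_a_finding(self, tmp_path):
        report = validate_table(tmp_path / "absent.csv", "marine_fresh")
        assert not report.passed
        assert report.findings[0].rule == "unreadable_file"
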