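"""Workbook I/O: input parsing, output layout, lossless round-trips."""

import csv
import random

import pytest
from openpyxl import Workbook, load_workbook

from phenocapture import (
    FixtureSpec,
    make_input_workbook,
    make_session,
    read_input,
    read_output,
    write_output,
)
from phenocapture.errors import (
    DuplicateShortcutError,
    MissingSheetError,
    NoValidLocationsError,
    PhenoIOError,
    UnknownTraitTypeError,
)
from phenocapture.model import LOCATION_COLUMNS, TRAIT_COLUMNS
from phenocapture.workbook import output_header


def write_raw_workbook(path, loc_rows, trait_rows):
    wb = Workbook()
    ws = wb.active
    ws.title = "Locations"
    ws.append(list(LOCATION_COLUMNS))
    for row in loc_rows:
        ws.append(row)
    ws2 = wb.create_sheet("Traits")
    ws2.append(list(TRAIT_COLUMNS))
    for row in trait_rows:
        ws2.append(row)
    wb.save(path)
    return path


class TestReadInput:
    def test_fixture_counts(self, tiny_spec, tmp_path):
        path = make_input_workbook(tiny_spec, tmp_path / "in.xlsx")
        book = read_input(path)
        assert len(book.locations) == 6
        assert len(book.descriptors) == 5
        assert book.observations == {}
        assert book.cursor.location_index == 0
        assert book.cursor.descriptor_shortcut == book.descriptors[0].shortcut

    def test_unknown_type_code_names_the_row(self, tmp_path):
        path = write_raw_workbook(
            tmp_path / "bad.xlsx",
            [["1", "1", "1"]],
            [["OK", "", 4, "", ""], ["BAD", "", 7, "", ""]],
        )
        with pytest.raises(UnknownTraitTypeError, match="row 3"):
            read_input(path)

    def test_alternative_key_row_loads(self, tmp_path):
        path = write_raw_workbook(
            tmp_path / "alt.xlsx",
            [["", "", "", "Riesling"]],
            [["T", "", 4, "", ""]],
        )
        book = read_input(path)
        assert len(book.locations) == 1
        assert not book.locations[0].uses_triple_key
        assert book.locations[0].accession_name == "Riesling"

    def test_invalid_rows_reported_with_row_numbers(self, tmp_path):
        path = write_raw_workbook(
            tmp_path / "mixed.xlsx",
            [["1", "1", "1"], ["1", "", "3"], ["1", "1", "1"]],
            [["T", "", 4, "", ""]],
        )
        book = read_input(path)
        assert len(book.locations) == 1
        assert any(r.startswith("row 3") for r in book.import_report)
        assert any("duplicate" in r and r.startswith("row 4") for r in book.import_report)

    def test_no_valid_locations(self, tmp_path):
        path = write_raw_workbook(
            tmp_path / "none.xlsx", [["1", "", ""]], [["T", "", 4, "", ""]]
        )
        with pytest.raises(NoValidLocationsError):
            read_input(path)

    def test_missing_sheet(self, tmp_path):
        wb = Workbook()
        wb.active.title = "OnlyOne"
        wb.save(tmp_path / "one.xlsx")
        with pytest.raises(MissingSheetError):
            read_input(tmp_path / "one.xlsx")

    def test_duplicate_shortcut(self, tmp_path):
        path = write_raw_workbook(
            tmp_path / "dup.xlsx",
            [["1", "1", "1"]],
            [["T", "", 4, "", ""], ["T", "", 2, "", ""]],
        )
        with pytest.raises(DuplicateShortcutError):
            read_input(path)

    def test_csv_pair_input(self, tmp_path):
        spec = FixtureSpec(seed=5)
        loc_path = make_input_workbook(spec, tmp_path / "trial.csv")
        book = read_input(loc_path)
        assert len(book.locations) == 6
        assert len(book.descriptors) == 5

    def test_xls_refused(self, tmp_path):
        with pytest.raises(PhenoIOError, match="xls"):
            read_input(tmp_path / "legacy.xls")

    def test_merged_accession_name_and_number_column(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "Locations"
        ws.append(["plot", "row", "plant", "accession name and number",
                   "variety number", "genotype", "mother", "father",
                   "information", "database-key"])
        ws.append(["1", "1", "1", "Riesling 4711", "", "", "", "", "", "DBK1"])
        ws2 = wb.create_sheet("Traits")
        ws2.append(list(TRAIT_COLUMNS))
        ws2.append(["T", "", 4, "", ""])
        wb.save(tmp_path / "merged.xlsx")
        book = read_input(tmp_path / "merged.xlsx")
        assert book.locations[0].accession_name == "Riesling 4711"
        assert book.locations[0].database_key == "DBK1"


class TestWriteOutput:
    def test_single_observation_cell(self, tiny_book, tmp_path):
        from phenocapture import record

        record(tiny_book, "3")
        out = write_output(tiny_book, tmp_path / "out.csv")
        rows = list(csv.reader(open(out, encoding="utf-8")))
        body = rows[1:]
        non_empty = [
            (i, j) for i, row in enumerate(body) for j, cell in enumerate(row[13:]) if cell
        ]
        assert non_empty == [(0, 0)]
        assert body[0][13] == "3"

    def test_remarks_fill_two_separate_columns(self, tiny_book, tmp_path):
        from phenocapture import set_remarks

        set_remarks(tiny_book, "north edge", "leaf damage")
        out = write_output(tiny_book, tmp_path / "out.csv")
        rows = list(csv.reader(open(out, encoding="utf-8")))
        assert rows[0][11:13] == ["location info", "plant note"]
        assert rows[1][11:13] == ["north edge", "leaf damage"]

    def test_column_arithmetic(self, tiny_book):
        header = output_header(tiny_book)
        assert len(header) == len(LOCATION_COLUMNS) + 2 + len(tiny_book.descriptors)

    def test_xlsx_dates_are_native(self, tiny_spec, tmp_path):
        import datetime

        book, _ = make_session(tiny_spec, tmp_path)
        idx = book.descriptor_index("DAT1")
        from phenocapture.model import Observation, TraitType

        book.observations[(0, "DAT1")] = Observation(
            TraitType.DATE, datetime.date(2022, 5, 17)
        )
        out = write_output(book, tmp_path / "out.xlsx")
        ws = load_workbook(out).worksheets[0]
        cell = ws.cell(row=2, column=len(LOCATION_COLUMNS) + 2 + idx + 1).value
        assert cell == datetime.datetime(2022, 5, 17)

    def test_unwritable_path(self, tiny_book):
        with pytest.raises(PhenoIOError):
            write_output(tiny_book, "/proc/definitely/not/writable/out.csv")


class TestRoundTrip:
    @staticmethod
    def roundtrip(spec, tmp_path, fmt):
        book, input_path = make_session(spec, tmp_path)
        out = write_output(book, tmp_path / f"out.{fmt}")
        restored = read_input(input_path)
        read_output(out, restored)
        return book, restored

    @pytest.mark.parametrize("fmt", ["csv", "xlsx"])
    def test_observations_and_locations_survive(self, tmp_path, fmt):
        spec = FixtureSpec(plots=2, rows_per_plot=2, plants_per_row=3,
                           fill_fraction=0.6, seed=9, n_alternative=2)
        book, restored = self.roundtrip(spec, tmp_path, fmt)
        assert [loc.as_row() for loc in restored.locations] == [
            loc.as_row() for loc in book.locations
        ]
        assert restored.observations == book.observations
        assert restored.import_report == []

    def test_csv_and_xlsx_decode_identically(self, tmp_path):
        spec = FixtureSpec(plots=3, rows_per_plot=2, plants_per_row=2,
                           fill_fraction=0.8, seed=13)
        book, input_path = make_session(spec, tmp_path)
        out_csv = write_output(book, tmp_path / "out.csv")
        out_xlsx = write_output(book, tmp_path / "out.xlsx")
        a = read_output(out_csv, read_input(input_path)).observations
        b = read_output(out_xlsx, read_input(input_path)).observations
        assert a == b == book.observations

    def test_fuzzed_small_books(self, tmp_path):
        rng = random.Random(99)
        for trial in range(10):
            spec = FixtureSpec(
                plots=rng.randint(1, 3),
                rows_per_plot=rng.randint(1, 3),
                plants_per_row=rng.randint(1, 4),
                fill_fraction=rng.random(),
                seed=trial,
            )
            sub = tmp_path / f"t{trial}"
            sub.mkdir()
            book, restored = self.roundtrip(spec, sub, "csv")
            assert restored.observations == book.observations

    def test_multi_value_cell_without_multiple_mode_is_flagged(self, tiny_spec, tmp_path):
        from phenocapture import Options, record

        book, input_path = make_session(
            tiny_spec, tmp_path, options=Options(multiple_selection=True)
        )
        record(book, "3,5")
        out = write_output(book, tmp_path / "out.csv")
        restored = read_input(input_path)  # default: multiple selection off
        read_output(out, restored)
        assert restored.observations == {}
        assert any("3,5" in entry for entry in restored.import_report)

    def test_empty_observation_columns_restore_to_empty_matrix(self, tiny_spec, tmp_path):
        book, input_path = make_session(tiny_spec, tmp_path)
        out = write_output(book, tmp_path / "out.xlsx")
        restored = read_input(input_path)
        read_output(out, restored)
        assert restored.observations == {}

    def test_database_key_passes_through_verbatim(self, tiny_spec, tmp_path):
        book, _ = make_session(tiny_spec, tmp_path)
        out = write_output(book, tmp_path / "out.csv")
        rows = list(csv.reader(open(out, encoding="utf-8")))
        keys = [row[10] for row in rows[1:]]
        assert keys == [loc.database_key for loc in book.locations]
        assert all(key.startswith("DBK") for key in keys)
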