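"""Workbook readers and writers.

Input: a two-sheet workbook — Locations first (11 fixed columns:
plot, row, plant, accession name, accession number, variety number,
genotype, mother, father, information, database-key), Traits second
(5 fixed columns: shortcut, description, type, values, remark). Sheets
are found by name when sheets named "Locations"/"Traits" exist, else by
position. The first row of each sheet is a header; unexpected header
strings warn but never fail. A CSV variant uses the file pair
``<name>_locations.csv`` + ``<name>_traits.csv``.

Output: one row per location in field-book order — all location columns
verbatim (including the hidden database-key), the two remark columns,
then one column per descriptor. XLSX stores measured values and dates as
native typed cells; CSV stores ISO-8601 dates and uses the standard
comma/double-quote dialect (UTF-8, LF).
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from pathlib import Path
from typing import List, Optional, Tuple

from .bbch import BBCHRegistry
from .errors import (
    ColumnMismatchError,
    DuplicateShortcutError,
    MissingSheetError,
    NoValidLocationsError,
    PhenoIOError,
    PhenoValidationError,
)
from .model import (
    LOCATION_COLUMNS,
    REMARK_COLUMNS,
    TRAIT_COLUMNS,
    FieldBook,
    LocationRecord,
    Options,
    Remarks,
    TraitDescriptor,
    TraitType,
    validate_location,
    validate_value,
)


def cell_text(value) -> str:
    """Normalize a spreadsheet cell to trimmed text.

    Integral floats lose the spurious ``.0`` a spreadsheet may attach to
    label columns; dates become ISO text.
    """
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    if isinstance(value, _dt.datetime):
        return value.date().isoformat() if value.time() == _dt.time() else value.isoformat()
    if isinstance(value, _dt.date):
        return value.isoformat()
    return str(value).strip()


def _is_empty_row(cells) -> bool:
    return all(cell_text(c) == "" for c in cells)


# -- raw table access (xlsx or csv) ------------------------------------------


def _load_tables(path) -> Tuple[List[list], List[list]]:
    """Return (locations_rows, traits_rows) including header rows."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xls":
        raise PhenoIOError(
            f"{path.name}: legacy .xls input is not supported; save as .xlsx or csv"
        )
    if suffix == ".csv":
        return _load_csv_pair(path)
    if not path.exists():
        raise PhenoIOError(f"input workbook {path} does not exist")
    from openpyxl import load_workbook

    wb = load_workbook(path, data_only=True)
    names = {str(ws.title).strip().casefold(): ws for ws in wb.worksheets}
    loc_ws = names.get("locations")
    trait_ws = names.get("traits")
    if loc_ws is None or trait_ws is None:
        if len(wb.worksheets) < 2:
            raise MissingSheetError(
                f"{path.name}: need a Locations and a Traits sheet, "
                f"found {len(wb.worksheets)} sheet(s)"
            )
        loc_ws = loc_ws or wb.worksheets[0]
        trait_ws = trait_ws or wb.worksheets[1]
    return (
        [list(r) for r in loc_ws.iter_rows(values_only=True)],
        [list(r) for r in trait_ws.iter_rows(values_only=True)],
    )


def csv_pair(path) -> Tuple[Path, Path]:
    """Resolve the two-file CSV input variant from either file or a stem."""
    path = Path(path)
    name = path.name
    if name.endswith("_locations.csv"):
        stem = name[: -len("_locations.csv")]
    elif name.endswith("_traits.csv"):
        stem = name[: -len("_traits.csv")]
    elif name.endswith(".csv"):
        stem = name[: -len(".csv")]
    else:
        stem = name
    base = path.parent
    return base / f"{stem}_locations.csv", base / f"{stem}_traits.csv"


def _load_csv_pair(path) -> Tuple[List[list], List[list]]:
    loc_path, trait_path = csv_pair(path)
    for p in (loc_path, trait_path):
        if not p.exists():
            raise PhenoIOError(f"CSV input part {p} does not exist")

    def read(p):
        with open(p, newline="", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh)]

    return read(loc_path), read(trait_path)


def _check_header(rows, expected, sheet: str, source) -> None:
    if not rows:
        return
    header = [cell_text(c).casefold() for c in rows[0]]
    want = [h.casefold() for h in expected]
    if header[: len(want)] != want:
        warnings.warn(
            f"{source}: {sheet} header {header[:len(want)]!r} differs from the "
            f"expected {list(want)!r}; parsing by column position",
            stacklevel=3,
        )


def _merged_name_number(rows) -> bool:
    """Detect the single merged 'accession name and number' column form."""
    if not rows:
        return False
    header = [cell_text(c).casefold() for c in rows[0]]
    return any("name and number" in h for h in header[:5])


# -- readers -----------------------------------------------------------------


def read_locations(rows, source="input") -> Tuple[List[LocationRecord], List[str]]:
    """Parse Locations rows (header included) into valid records plus a
    report of rejected rows with their 1-based row numbers."""
    records: List[LocationRecord] = []
    report: List[str] = []
    merged = _merged_name_number(rows)
    with warnings.catch_warnings():
        if merged:
            warnings.simplefilter("ignore")
        _check_header(rows, LOCATION_COLUMNS, "Locations", source)
    seen_triples = set()
    for row_no, cells in enumerate(rows[1:], start=2):
        if _is_empty_row(cells):
            continue
        texts = [cell_text(c) for c in cells]
        if merged:
            # split point: merged column sits at position 3; number stays empty
            texts = texts[:4] + [""] + texts[4:]
        record = LocationRecord.from_row(texts)
        verdict = validate_location(record)
        if not verdict:
            report.append(f"row {row_no}: {verdict.reason}")
            continue
        if record.uses_triple_key:
            if record.key in seen_triples:
                report.append(
                    f"row {row_no}: duplicate location {' '.join(record.key)}"
                )
                continue
            seen_triples.add(record.key)
        records.append(record)
    return records, report


def read_traits(rows, source="input") -> List[TraitDescriptor]:
    _check_header(rows, TRAIT_COLUMNS, "Traits", source)
    descriptors: List[TraitDescriptor] = []
    seen = set()
    for row_no, cells in enumerate(rows[1:], start=2):
        if _is_empty_row(cells):
            continue
        texts = [cell_text(c) for c in cells]
        texts += [""] * (len(TRAIT_COLUMNS) - len(texts))
        shortcut, description, type_code, values_raw, remark = texts[: len(TRAIT_COLUMNS)]
        if not shortcut:
            raise PhenoValidationError(f"{source}: Traits row {row_no} has no shortcut")
        if shortcut in seen:
            raise DuplicateShortcutError(
                f"{source}: duplicate trait shortcut {shortcut!r} in row {row_no}"
            )
        seen.add(shortcut)
        try:
            trait_type = TraitType.from_code(type_code)
            descriptors.append(
                TraitDescriptor(
                    shortcut=shortcut,
                    description=description,
                    trait_type=trait_type,
                    values_raw=values_raw,
                    remark=remark,
                )
            )
        except PhenoValidationError as exc:
            raise type(exc)(f"{source}: Traits row {row_no}: {exc}") from None
    return descriptors


def read_input(
    path,
    options: Optional[Options] = None,
    registry: Optional[BBCHRegistry] = None,
) -> FieldBook:
    """Read an input workbook into a fresh field book.

    Locations are validated row by row (rejects land in
    ``book.import_report`` with their row numbers); the observation
    matrix starts empty and the cursor sits on the first location of the
    traversal plan, first descriptor.
    """
    loc_rows, trait_rows = _load_tables(path)
    source = Path(path).name
    records, report = read_locations(loc_rows, source)
    if not records:
        raise NoValidLocationsError(f"{source}: no valid location rows")
    descriptors = read_traits(trait_rows, source)
    book = FieldBook(
        locations=records,
        descriptors=descriptors,
        options=options or Options(),
        registry=registry or BBCHRegistry.with_builtin(),
        import_report=report,
    )
    book.reset_cursor()
    return book


# -- writer ------------------------------------------------------------------


def output_header(book: FieldBook) -> List[str]:
    return (
        list(LOCATION_COLUMNS)
        + list(REMARK_COLUMNS)
        + [d.shortcut for d in book.descriptors]
    )


def _output_rows(book: FieldBook, dialect: str):
    for i, loc in enumerate(book.locations):
        remarks = book.remarks.get(i, Remarks())
        row = list(loc.as_row()) + [remarks.location_info, remarks.plant_note]
        for d in book.descriptors:
            obs = book.observations.get((i, d.shortcut))
            row.append("" if obs is None else obs.serialize(dialect))
        yield row


def write_output(book: FieldBook, path, fmt: Optional[str] = None) -> Path:
    """Write the output table (xlsx or csv, inferred from the suffix when
    ``fmt`` is not given)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("xlsx", "csv"):
        raise PhenoIOError(f"unsupported output format {fmt!r} (xlsx or csv)")
    header = output_header(book)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(header)
                writer.writerows(_output_rows(book, "csv"))
        else:
            from openpyxl import Workbook

            wb = Workbook()
            ws = wb.active
            ws.title = "Output"
            ws.append(header)
            for row in _output_rows(book, "xlsx"):
                ws.append(row)
            wb.save(path)
    except OSError as exc:
        raise PhenoIOError(f"cannot write {path}: {exc}") from exc
    return path


# -- output reader (session resume) ------------------------------------------


def _load_output_rows(path) -> List[list]:
    path = Path(path)
    if not path.exists():
        raise PhenoIOError(f"output file {path} does not exist")
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh)]
    from openpyxl import load_workbook

    wb = load_workbook(path, data_only=True)
    return [list(r) for r in wb.worksheets[0].iter_rows(values_only=True)]


def read_output(path, book: FieldBook) -> FieldBook:
    """Restore observations and remarks from an output file into ``book``.

    The file must match the book: same descriptor columns, rows in
    field-book location order. Every non-empty cell is re-validated;
    failures are collected in ``book.import_report`` (value retained in
    the report) rather than dropped silently.
    """
    rows = _load_output_rows(path)
    if not rows:
        raise ColumnMismatchError(f"{Path(path).name}: empty output file")
    header = [cell_text(c) for c in rows[0]]
    expected = output_header(book)
    if [h.casefold() for h in header] != [h.casefold() for h in expected]:
        raise ColumnMismatchError(
            f"{Path(path).name}: columns do not match the field book "
            f"(expected {len(expected)} columns ending in the descriptor "
            "shortcuts)"
        )
    n_loc_cols = len(LOCATION_COLUMNS)
    data_rows = [r for r in rows[1:] if not _is_empty_row(r)]
    if len(data_rows) != len(book.locations):
        raise ColumnMismatchError(
            f"{Path(path).name}: {len(data_rows)} rows for "
            f"{len(book.locations)} locations"
        )
    book.observations.clear()
    book.remarks.clear()
    for i, cells in enumerate(data_rows):
        cells = list(cells) + [None] * (len(expected) - len(cells))
        loc_info = cell_text(cells[n_loc_cols])
        plant_note = cell_text(cells[n_loc_cols + 1])
        if loc_info or plant_note:
            book.remarks[i] = Remarks(loc_info, plant_note)
        for j, descriptor in enumerate(book.descriptors):
            raw = cells[n_loc_cols + 2 + j]
            if raw is None or (isinstance(raw, str) and not raw.strip()):
                continue
            try:
                obs = validate_value(
                    descriptor,
                    raw,
                    multiple=book.options.multiple_selection,
                    registry=book.registry,
                    strict_scale=book.options.strict_scale,
                )
            except PhenoValidationError as exc:
                book.import_report.append(
                    f"row {i + 2}, {descriptor.shortcut}: rejected value "
                    f"{cell_text(raw)!r} ({exc})"
                )
                continue
            book.observations[(i, descriptor.shortcut)] = obs
    return book
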