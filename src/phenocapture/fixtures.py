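"""Deterministic generator of synthetic field layouts, descriptor sets,
BBCH templates and partially filled sessions.

All content is synthetic and flows from one seeded ``random.Random``; the
same spec and seed reproduce byte-identical files (xlsx zip metadata is
rewritten with a constant timestamp to that end). Generated fixtures are
guaranteed to pass the full validation stack: every location satisfies
the obligatory-column rule and every generated observation validates
against its descriptor.
"""

from __future__ import annotations

import datetime as _dt
import random
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .bbch import BBCHRegistry, export_template, make_fixture_scale
from .errors import PhenoValidationError
from .model import (
    LOCATION_COLUMNS,
    TRAIT_COLUMNS,
    FieldBook,
    Options,
    TraitType,
    validate_value,
)
from .workbook import read_locations, read_traits

#: The worked rating-scale example used for every generated type-1 descriptor.
EXAMPLE_SCALE = "1: none; 3: little; 5: medium; 7: strong; 9: very strong"

_NAMES = (
    "Riesling", "Regent", "Chardonnay", "Phoenix", "Solaris", "Kerner",
    "Dornfelder", "Calandro", "Villaris", "Felicia",
)
_WORDS = (
    "vigorous", "compact", "late", "early", "glossy", "hairy", "serrated",
    "upright", "drooping", "dense",
)

_ZIP_EPOCH = (2000, 1, 1, 0, 0, 0)
_DOC_EPOCH = _dt.datetime(2000, 1, 1)


def _freeze_xlsx(path: Path) -> None:
    """Rewrite an xlsx so its bytes depend only on content, not on the
    wall clock (zip entry timestamps)."""
    path = Path(path)
    with zipfile.ZipFile(path) as zin:
        entries = [(info.filename, zin.read(info.filename)) for info in zin.infolist()]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for name, data in entries:
            info = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zout.writestr(info, data)


def _freeze_properties(wb) -> None:
    wb.properties.created = _DOC_EPOCH
    wb.properties.modified = _DOC_EPOCH
    wb.properties.creator = "phenocapture"
    wb.properties.lastModifiedBy = "phenocapture"


@dataclass
class FixtureSpec:
    """Shape of a synthetic trial.

    rows_per_plot / plants_per_row accept a single count or a list (per
    plot, respectively per row across all plots in order) so ragged
    layouts can be generated. descriptor_mix maps trait-type code to the
    number of descriptors of that type.
    """

    plots: int = 2
    rows_per_plot: Union[int, List[int]] = 1
    plants_per_row: Union[int, List[int]] = 3
    descriptor_mix: Dict[int, int] = field(
        default_factory=lambda: {1: 1, 2: 1, 3: 1, 4: 1, 5: 1}
    )
    fill_fraction: float = 0.0
    seed: int = 0
    n_alternative: int = 0  # extra accession-name-only records

    def __post_init__(self):
        if self.plots < 1:
            raise PhenoValidationError("fixture needs at least one plot")
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise PhenoValidationError("fill_fraction must be in [0, 1]")


def _grid(spec: FixtureSpec) -> List[Tuple[str, str, str]]:
    rows_per_plot = (
        list(spec.rows_per_plot)
        if isinstance(spec.rows_per_plot, (list, tuple))
        else [spec.rows_per_plot] * spec.plots
    )
    if len(rows_per_plot) != spec.plots:
        raise PhenoValidationError("rows_per_plot list length must equal plots")
    total_rows = sum(rows_per_plot)
    plants_per_row = (
        list(spec.plants_per_row)
        if isinstance(spec.plants_per_row, (list, tuple))
        else [spec.plants_per_row] * total_rows
    )
    if len(plants_per_row) != total_rows:
        raise PhenoValidationError(
            "plants_per_row list length must equal the total number of rows"
        )
    if any(n < 1 for n in rows_per_plot) or any(n < 1 for n in plants_per_row):
        raise PhenoValidationError("zero-size grid: counts must be positive")
    grid = []
    row_cursor = 0
    for p in range(1, spec.plots + 1):
        for r in range(1, rows_per_plot[p - 1] + 1):
            for q in range(1, plants_per_row[row_cursor] + 1):
                grid.append((str(p), str(r), str(q)))
            row_cursor += 1
    return grid


def _location_rows(spec: FixtureSpec, rng: random.Random) -> List[list]:
    rows = [list(LOCATION_COLUMNS)]
    counter = 0
    for plot, row, plant in _grid(spec):
        counter += 1
        name = rng.choice(_NAMES)
        rows.append([
            plot, row, plant,
            name,
            f"ACC-{rng.randrange(10000):04d}",
            f"VAR-{rng.randrange(1000):03d}",
            f"G{rng.randrange(100):02d}",
            rng.choice(_NAMES),
            rng.choice(_NAMES),
            rng.choice(_WORDS),
            f"DBK{counter:06d}",
        ])
    for _ in range(spec.n_alternative):
        counter += 1
        rows.append([
            "", "", "",
            f"{rng.choice(_NAMES)}-{rng.randrange(100):02d}",
            f"ACC-{rng.randrange(10000):04d}",
            "", "", "", "", "",
            f"DBK{counter:06d}",
        ])
    return rows


_TYPE_TAGS = {1: "RAT", 2: "MEA", 3: "DAT", 4: "TXT", 5: "BBCH"}


def _trait_rows(spec: FixtureSpec) -> List[list]:
    rows = [list(TRAIT_COLUMNS)]
    for code in sorted(spec.descriptor_mix):
        if code not in _TYPE_TAGS:
            raise PhenoValidationError(f"descriptor_mix has unknown type code {code}")
        for k in range(1, spec.descriptor_mix[code] + 1):
            shortcut = f"{_TYPE_TAGS[code]}{k}"
            values = EXAMPLE_SCALE if code == 1 else ""
            remark = "cm" if code == 2 else ""
            rows.append([shortcut, f"synthetic type-{code} descriptor", code, values, remark])
    if len(rows) == 1:
        raise PhenoValidationError("descriptor_mix yields no descriptors")
    return rows


# -- file generators ---------------------------------------------------------


def make_input_workbook(spec: FixtureSpec, path) -> Path:
    """Write a synthetic input workbook (xlsx, or the CSV pair when the
    path ends in .csv)."""
    rng = random.Random(spec.seed)
    loc_rows = _location_rows(spec, rng)
    trait_rows = _trait_rows(spec)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        import csv as _csv

        from .workbook import csv_pair

        loc_path, trait_path = csv_pair(path)
        for target, rows in ((loc_path, loc_rows), (trait_path, trait_rows)):
            with open(target, "w", newline="", encoding="utf-8") as fh:
                _csv.writer(fh, lineterminator="\n").writerows(rows)
        return loc_path
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "Locations"
    for row in loc_rows:
        ws.append(row)
    ws2 = wb.create_sheet("Traits")
    for row in trait_rows:
        ws2.append(row)
    _freeze_properties(wb)
    wb.save(path)
    _freeze_xlsx(path)
    return path


def make_bbch_template(
    species: str,
    n_principal: int,
    specifics_per_principal: int,
    seed: int,
    path,
) -> Path:
    """Write a structurally valid synthetic BBCH template workbook."""
    if not 1 <= n_principal <= 10:
        raise PhenoValidationError("n_principal must be between 1 and 10")
    if not 1 <= specifics_per_principal <= 10:
        raise PhenoValidationError("specifics_per_principal must be between 1 and 10")
    rng = random.Random(seed)
    from .bbch import BBCHScale, PrincipalStage, SpecificStage

    principals = [
        PrincipalStage(code=str(d), title=f"{species} stage {d} ({rng.choice(_WORDS)})")
        for d in range(n_principal)
    ]
    specifics = {
        str(d): [
            SpecificStage(code=f"{d}{j}", description=f"{species} step {d}{j}")
            for j in range(specifics_per_principal)
        ]
        for d in range(n_principal)
    }
    scale = BBCHScale(species=species, principal_stages=principals, specific_stages=specifics)
    path = export_template(scale, path)
    _freeze_xlsx(path)
    return path


# -- in-memory session generator ---------------------------------------------


def _draw_value(descriptor, rng: random.Random, bbch_codes: List[str]) -> str:
    t = descriptor.trait_type
    if t == TraitType.RATING:
        return rng.choice(descriptor.scale.codes)
    if t == TraitType.MEASURED:
        return str(round(rng.uniform(0.1, 99.9), 1))
    if t == TraitType.DATE:
        return (_dt.date(2022, 5, 1) + _dt.timedelta(days=rng.randrange(60))).isoformat()
    if t == TraitType.TEXT:
        return f"{rng.choice(_WORDS)} {rng.choice(_WORDS)}"
    return f"grapevine-fixture:{rng.choice(bbch_codes)}"


def fill_fieldbook(book: FieldBook, fill_fraction: float, seed: int) -> FieldBook:
    """Record exactly round(fill_fraction x cells) observations with
    seeded, per-type valid values (over all descriptors)."""
    rng = random.Random(seed ^ 0x5EED)
    cells = [
        (i, d) for i in range(len(book.locations)) for d in book.descriptors
    ]
    n = round(fill_fraction * len(cells))
    bbch_codes = sorted(make_fixture_scale("grapevine").codes())
    for i, descriptor in rng.sample(cells, n):
        raw = _draw_value(descriptor, rng, bbch_codes)
        book.observations[(i, descriptor.shortcut)] = validate_value(
            descriptor, raw, registry=book.registry
        )
    return book


def make_fieldbook(spec: FixtureSpec, options: Optional[Options] = None) -> FieldBook:
    """Build a validated, partially filled field book entirely in memory
    (same content the workbook generator writes to disk)."""
    rng = random.Random(spec.seed)
    records, report = read_locations(_location_rows(spec, rng), "fixture")
    if report:
        raise PhenoValidationError(f"fixture generated invalid locations: {report}")
    descriptors = read_traits(_trait_rows(spec), "fixture")
    book = FieldBook(
        locations=records,
        descriptors=descriptors,
        options=options or Options(),
        registry=BBCHRegistry.with_builtin(),
    )
    book.reset_cursor()
    return fill_fieldbook(book, spec.fill_fraction, spec.seed)


def make_session(spec: FixtureSpec, directory, options: Optional[Options] = None):
    """Write the input workbook into ``directory``, read it back and fill
    it; returns (fieldbook, input path)."""
    from .workbook import read_input

    directory = Path(directory)
    input_path = make_input_workbook(spec, directory / "fixture_input.xlsx")
    book = read_input(input_path, options=options)
    fill_fieldbook(book, spec.fill_fraction, spec.seed)
    return book, input_path
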