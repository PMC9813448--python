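"""Domain model: locations, trait descriptors, the five trait types,
rating scales, observations and the field book.

The field book mirrors the classical field notebook used in genebank
characterization and breeding trials: an ordered list of plant locations
(plot / row / plant, plus passport metadata), an ordered list of scored
descriptors, and a sparse matrix of observations. Five trait types are
supported:

1. rating          — categorical score against a defined scale
2. measured value  — decimal number (units go in the descriptor remark)
3. date            — calendar date
4. text            — free text
5. bbch            — phenological growth stage on a BBCH scale

Rating scales are written in the descriptor's values column as
``1: none; 3: little; 5: medium; 7: strong; 9: very strong`` — entries
separated by ";", code split from label at the first ":".
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .errors import (
    DuplicateScaleCodeError,
    MalformedScaleEntryError,
    MissingScaleError,
    MultipleNotAllowedError,
    NonNumericValueError,
    OutOfScaleError,
    UnknownSpeciesError,
    UnknownTraitTypeError,
    UnparseableDateError,
)

#: Column order of the Locations sheet. The last column (database-key) is
#: never shown in listings but is copied verbatim to the output file.
LOCATION_COLUMNS = (
    "plot",
    "row",
    "plant",
    "accession name",
    "accession number",
    "variety number",
    "genotype",
    "mother",
    "father",
    "information",
    "database-key",
)

#: Column order of the Traits sheet.
TRAIT_COLUMNS = ("shortcut", "description", "type", "values", "remark")

#: Headers of the two remark columns in the output table.
REMARK_COLUMNS = ("location info", "plant note")


class TraitType(enum.IntEnum):
    """The five trait-type codes of the descriptor schema."""

    RATING = 1
    MEASURED = 2
    DATE = 3
    TEXT = 4
    BBCH = 5

    @classmethod
    def from_code(cls, code) -> "TraitType":
        try:
            value = int(str(code).strip())
        except (TypeError, ValueError):
            raise UnknownTraitTypeError(f"trait type code {code!r} is not an integer")
        try:
            return cls(value)
        except ValueError:
            raise UnknownTraitTypeError(
                f"trait type code {value} is outside the accepted range 1-5"
            )


@dataclass(frozen=True)
class LocationRecord:
    """One plant position with its passport fields.

    Either the triple key (plot, row, plant) is complete, or the record
    runs in alternative-key mode identified by ``accession_name`` alone.
    """

    plot: str = ""
    row: str = ""
    plant: str = ""
    accession_name: str = ""
    accession_number: str = ""
    variety_number: str = ""
    genotype: str = ""
    mother: str = ""
    father: str = ""
    information: str = ""
    database_key: str = ""

    @property
    def uses_triple_key(self) -> bool:
        return bool(self.plot.strip() and self.row.strip() and self.plant.strip())

    @property
    def key(self) -> tuple:
        if self.uses_triple_key:
            return (self.plot.strip(), self.row.strip(), self.plant.strip())
        return (self.accession_name.strip(),)

    def as_row(self) -> tuple:
        """Values in Locations-sheet column order."""
        return (
            self.plot,
            self.row,
            self.plant,
            self.accession_name,
            self.accession_number,
            self.variety_number,
            self.genotype,
            self.mother,
            self.father,
            self.information,
            self.database_key,
        )

    @classmethod
    def from_row(cls, cells) -> "LocationRecord":
        cells = [("" if c is None else str(c).strip()) for c in cells]
        cells += [""] * (len(LOCATION_COLUMNS) - len(cells))
        return cls(*cells[: len(LOCATION_COLUMNS)])

    def label(self) -> str:
        if self.uses_triple_key:
            return " ".join(self.key)
        return self.accession_name.strip()


@dataclass(frozen=True)
class Verdict:
    """Validity verdict with a human-readable reason."""

    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.valid


def validate_location(record: LocationRecord) -> Verdict:
    """Check the obligatory-column rule.

    A record is valid iff (plot, row, plant) are all non-empty after
    trimming, or — the alternative mode — accession name alone is
    non-empty.
    """
    if record.uses_triple_key:
        return Verdict(True, "triple key")
    if record.accession_name.strip():
        return Verdict(True, "accession-name key")
    missing = [
        name
        for name, val in zip(("plot", "row", "plant"), (record.plot, record.row, record.plant))
        if not val.strip()
    ]
    return Verdict(
        False,
        f"incomplete triple key (missing {', '.join(missing)}) and no accession name",
    )


@dataclass(frozen=True)
class RatingScale:
    """Ordered categorical scale: (code, label) pairs."""

    entries: tuple

    @property
    def codes(self) -> tuple:
        return tuple(code for code, _ in self.entries)

    def to_raw(self) -> str:
        """Serialize back to the values-column grammar."""
        return "; ".join(f"{code}: {label}" for code, label in self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.codes


def parse_rating_scale(values_raw: str) -> RatingScale:
    """Parse a values-column scale string.

    Entries split on ";", each entry split on the first ":" into
    (code, label); all tokens are trimmed and order is preserved.
    """
    if values_raw is None or not str(values_raw).strip():
        raise MissingScaleError("rating descriptor has an empty values column")
    entries = []
    seen = set()
    for chunk in str(values_raw).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" not in chunk:
            raise MalformedScaleEntryError(
                f"scale entry {chunk!r} lacks the 'code: label' form"
            )
        code, label = chunk.split(":", 1)
        code = code.strip()
        label = label.strip()
        if not code:
            raise MalformedScaleEntryError(f"scale entry {chunk!r} has an empty code")
        if "," in code:
            raise MalformedScaleEntryError(
                f"scale code {code!r} contains ',' which is reserved as the "
                "multiple-selection list separator"
            )
        if code in seen:
            raise DuplicateScaleCodeError(f"duplicate scale code {code!r}")
        seen.add(code)
        entries.append((code, label))
    if not entries:
        raise MissingScaleError("rating descriptor has an empty values column")
    return RatingScale(tuple(entries))


@dataclass
class TraitDescriptor:
    """One scored descriptor (a row of the Traits sheet)."""

    shortcut: str
    description: str = ""
    trait_type: TraitType = TraitType.TEXT
    values_raw: str = ""
    remark: str = ""
    selected: bool = True
    scale: Optional[RatingScale] = None

    def __post_init__(self):
        if self.trait_type == TraitType.RATING and self.scale is None:
            self.scale = parse_rating_scale(self.values_raw)

    def as_row(self) -> tuple:
        return (
            self.shortcut,
            self.description,
            int(self.trait_type),
            self.values_raw,
            self.remark,
        )


@dataclass(frozen=True)
class BBCHObservationCode:
    """A recorded growth stage: species plus two-digit code."""

    species: str
    code: str

    def serialize(self) -> str:
        return f"{self.species}:{self.code}"


#: Payload union of an observation, tagged by TraitType.
Payload = Union[list, float, _dt.date, str, BBCHObservationCode]


@dataclass(frozen=True)
class Observation:
    """The recorded value for one (location, descriptor) cell."""

    kind: TraitType
    value: Payload

    def serialize(self, dialect: str = "csv"):
        """Cell representation for the output table.

        ``dialect`` "csv" yields text (ISO dates, repr floats);
        "xlsx" yields native Python objects for typed cells.
        """
        if self.kind == TraitType.RATING:
            return ",".join(self.value)
        if self.kind == TraitType.MEASURED:
            if dialect == "xlsx":
                return self.value
            return format_number(self.value)
        if self.kind == TraitType.DATE:
            if dialect == "xlsx":
                return self.value
            return self.value.isoformat()
        if self.kind == TraitType.BBCH:
            return self.value.serialize()
        return self.value


def format_number(x: float) -> str:
    """Minimal decimal text that parses back to the same float."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


@dataclass
class Remarks:
    """The two free-text note fields attached to one location.

    They map to two distinct output columns and are never concatenated.
    """

    location_info: str = ""
    plant_note: str = ""


def parse_date(raw) -> _dt.date:
    if isinstance(raw, _dt.datetime):
        return raw.date()
    if isinstance(raw, _dt.date):
        return raw
    text = str(raw).strip()
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        pass
    # common spreadsheet forms: 31.05.2022 and 31/05/2022
    for fmt in ("%d.%m.%Y", "%d/%m/%Y"):
        try:
            return _dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise UnparseableDateError(f"cannot parse {text!r} as a calendar date")


def validate_value(
    descriptor: TraitDescriptor,
    raw,
    multiple: bool = False,
    *,
    registry=None,
    species: Optional[str] = None,
    strict_scale: bool = True,
) -> Observation:
    """Validate a raw entry against its descriptor and build an Observation.

    Total over its inputs: every (descriptor, raw) pair yields either an
    Observation or a typed PhenoValidationError, never a crash.

    Parameters
    ----------
    multiple : whether multiple-selection mode is active (type 1 only);
        comma-separated tokens are rejected otherwise.
    registry : BBCH registry used to validate type-5 codes. When absent,
        only the two-digit form is checked.
    species : sticky species context for type-5 entries given as a bare
        code; a fully qualified ``species:code`` entry overrides it.
    strict_scale : reject rating tokens outside the descriptor's scale
        (default). Disabling stores off-scale tokens as-is.
    """
    t = descriptor.trait_type
    if t == TraitType.RATING:
        text = raw if isinstance(raw, str) else str(raw)
        tokens = [tok.strip() for tok in text.split(",")]
        if any(not tok for tok in tokens):
            raise OutOfScaleError(f"empty rating token in {text!r}")
        if len(tokens) > 1 and not multiple:
            raise MultipleNotAllowedError(
                f"{text!r} holds multiple values but multiple selection is off"
            )
        if strict_scale:
            scale = descriptor.scale
            for tok in tokens:
                if tok not in scale:
                    raise OutOfScaleError(
                        f"rating {tok!r} is not on the scale of "
                        f"{descriptor.shortcut!r} (codes: {', '.join(scale.codes)})"
                    )
        return Observation(t, tokens)

    if t == TraitType.MEASURED:
        if isinstance(raw, bool):
            raise NonNumericValueError(f"{raw!r} is not a decimal number")
        if isinstance(raw, (int, float)):
            value = float(raw)
        else:
            text = str(raw).strip()
            if "," in text:
                raise NonNumericValueError(
                    f"{text!r}: ',' is reserved as the list separator; "
                    "use '.' as the decimal separator"
                )
            try:
                value = float(text)
            except ValueError:
                raise NonNumericValueError(f"{text!r} is not a decimal number")
        if not math.isfinite(value):
            raise NonNumericValueError(f"{raw!r} is not a finite number")
        return Observation(t, value)

    if t == TraitType.DATE:
        return Observation(t, parse_date(raw))

    if t == TraitType.TEXT:
        return Observation(t, str(raw))

    # BBCH
    if isinstance(raw, BBCHObservationCode):
        sp, code = raw.species, raw.code
    else:
        text = str(raw).strip()
        if ":" in text:
            sp, code = (part.strip() for part in text.split(":", 1))
        else:
            sp, code = species, text
    if not sp:
        raise UnknownSpeciesError(
            f"BBCH entry {raw!r} carries no species and no species context is set"
        )
    if registry is not None:
        return Observation(t, registry.validate_code(sp, code))
    from .bbch import check_code_shape  # local import avoids a cycle

    check_code_shape(code)
    return Observation(t, BBCHObservationCode(sp, code))


@dataclass
class Options:
    """Session options mirroring the app settings."""

    zigzag: bool = False
    multiple_selection: bool = False
    bbch_question: bool = False
    strict_scale: bool = True
    zigzag_carry: bool = False


@dataclass
class Cursor:
    """Position in the (location x selected-descriptor) grid.

    ``at_end`` marks the defined end-state reached by advancing past the
    last cell of the traversal plan.
    """

    location_index: int = 0
    descriptor_shortcut: str = ""
    direction: str = "forward"
    at_end: bool = False

    def copy(self) -> "Cursor":
        return replace(self)


@dataclass
class FieldBook:
    """One phenotyping session.

    observations maps (location index, descriptor shortcut) to an
    Observation; remarks maps location index to the two note fields.
    """

    locations: list = field(default_factory=list)
    descriptors: list = field(default_factory=list)
    observations: dict = field(default_factory=dict)
    remarks: dict = field(default_factory=dict)
    options: Options = field(default_factory=Options)
    cursor: Cursor = field(default_factory=Cursor)
    registry: object = None
    species_context: Optional[str] = None
    audit_log: list = field(default_factory=list)
    import_report: list = field(default_factory=list)

    # -- descriptor helpers --------------------------------------------------

    def descriptor(self, shortcut: str) -> TraitDescriptor:
        for d in self.descriptors:
            if d.shortcut == shortcut:
                return d
        raise KeyError(shortcut)

    def descriptor_index(self, shortcut: str) -> int:
        for i, d in enumerate(self.descriptors):
            if d.shortcut == shortcut:
                return i
        raise KeyError(shortcut)

    @property
    def selected_descriptors(self) -> list:
        return [d for d in self.descriptors if d.selected]

    def current_descriptor(self) -> TraitDescriptor:
        return self.descriptor(self.cursor.descriptor_shortcut)

    def current_location(self) -> LocationRecord:
        return self.locations[self.cursor.location_index]

    # -- observation helpers -------------------------------------------------

    def observation_at(self, location_index: int, shortcut: str):
        return self.observations.get((location_index, shortcut))

    def is_complete(self) -> bool:
        return all(
            (i, d.shortcut) in self.observations
            for i in range(len(self.locations))
            for d in self.selected_descriptors
        )

    def add_descriptor(self, descriptor: TraitDescriptor) -> None:
        from .errors import DuplicateShortcutError

        if any(d.shortcut == descriptor.shortcut for d in self.descriptors):
            raise DuplicateShortcutError(
                f"descriptor shortcut {descriptor.shortcut!r} already exists"
            )
        self.descriptors.append(descriptor)

    def reset_cursor(self) -> None:
        """Place the cursor on the first location of the traversal plan,
        first selected descriptor."""
        from .navigation import traversal_plan

        plan = traversal_plan(self)
        selected = self.selected_descriptors
        if plan.sequence and selected:
            self.cursor = Cursor(plan.sequence[0], selected[0].shortcut)
        else:
            self.cursor = Cursor(at_end=True)
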