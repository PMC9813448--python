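"""The recording engine: validated data entry at the cursor, quick dates,
remarks, photo file names, dated BBCH columns and partial selection.

All operations mutate the FieldBook in place and return the new cursor
(or the book) so CLI and scripts can chain them. ``record`` is atomic: a
validation failure leaves the book — matrix, remarks, cursor — untouched.
"""

from __future__ import annotations

import datetime as _dt
import re
from typing import Iterable, Optional, Union

from . import navigation
from .errors import (
    AlreadyExistsError,
    PhenoValidationError,
    UnknownLocationError,
    UnknownShortcutError,
)
from .model import (
    Cursor,
    FieldBook,
    Remarks,
    TraitDescriptor,
    TraitType,
    validate_value,
)

#: Quick-date buttons: day before yesterday … day after tomorrow.
QUICK_DATE_OFFSETS = (-2, -1, 0, 1, 2)


def record(book: FieldBook, raw) -> Cursor:
    """Validate ``raw`` against the cursor's descriptor and store it.

    The cursor auto-advances to the next selected descriptor (next
    location after the last one) unless multiple selection is active, in
    which case it stays put so further values can be added to the same
    cell. Re-recording an already-filled cell overwrites it and logs the
    overwrite in ``book.audit_log``. On a validation error nothing is
    stored and the cursor does not move.
    """
    cur = book.cursor
    if cur.at_end:
        raise PhenoValidationError("cursor is at the end-state; nothing to record")
    descriptor = book.current_descriptor()
    obs = validate_value(
        descriptor,
        raw,
        multiple=book.options.multiple_selection,
        registry=book.registry,
        species=book.species_context,
        strict_scale=book.options.strict_scale,
    )
    key = (cur.location_index, descriptor.shortcut)
    previous = book.observations.get(key)
    if previous is not None:
        book.audit_log.append(
            f"overwrite {book.locations[cur.location_index].label()} "
            f"{descriptor.shortcut}: {previous.serialize()!r} -> {obs.serialize()!r}"
        )
    book.observations[key] = obs
    if obs.kind == TraitType.BBCH:
        book.species_context = obs.value.species  # sticky for the session
    if not book.options.multiple_selection:
        book.cursor = navigation.advance(book)
    return book.cursor


def quick_date(
    offset_or_date: Union[int, _dt.date, str],
    today: Optional[_dt.date] = None,
) -> _dt.date:
    """Resolve a quick-date button or an explicit date.

    Integer offsets in -2..+2 map to the five buttons (day before
    yesterday, yesterday, today, tomorrow, day after tomorrow); anything
    else must be an explicit calendar date.
    """
    if isinstance(offset_or_date, bool):
        raise PhenoValidationError("quick date takes an offset or a date")
    if isinstance(offset_or_date, int):
        if offset_or_date not in QUICK_DATE_OFFSETS:
            raise PhenoValidationError(
                f"quick-date offset {offset_or_date} outside -2..+2; "
                "pass an explicit date instead"
            )
        base = today if today is not None else _dt.date.today()
        return base + _dt.timedelta(days=offset_or_date)
    from .model import parse_date

    return parse_date(offset_or_date)


def set_remarks(book: FieldBook, location_info: str = "", plant_note: str = "") -> FieldBook:
    """Store the two note fields for the cursor's location.

    The merge is field-wise: an empty argument leaves that field as it
    was, so the two notes can be edited independently.
    """
    if not location_info and not plant_note:
        return book
    idx = book.cursor.location_index
    current = book.remarks.get(idx, Remarks())
    book.remarks[idx] = Remarks(
        location_info=location_info if location_info else current.location_info,
        plant_note=plant_note if plant_note else current.plant_note,
    )
    return book


_UNSAFE = re.compile(r'[\\/:*?"<>|\x00-\x1f]')


def _sanitize(part: str) -> str:
    part = part.strip().replace(" ", "-")
    return _UNSAFE.sub("", part)


def photo_name(book: FieldBook, timestamp: _dt.datetime) -> str:
    """File name for a photo taken at the cursor's location.

    ``<plot>-<row>-<plant>_<YYYYMMDD-HHMMSS>[_<variety>]``; alternative-key
    locations use the accession name as the location part (and therefore
    carry no separate variety part). Spaces become "-", filesystem-reserved
    characters are stripped.
    """
    loc = book.current_location()
    stamp = timestamp.strftime("%Y%m%d-%H%M%S")
    if loc.uses_triple_key:
        location_part = _sanitize(f"{loc.plot.strip()}-{loc.row.strip()}-{loc.plant.strip()}")
        variety = _sanitize(loc.accession_name)
        if variety:
            return f"{location_part}_{stamp}_{variety}"
        return f"{location_part}_{stamp}"
    return f"{_sanitize(loc.accession_name)}_{stamp}"


def add_dated_bbch_descriptor(book: FieldBook, date: _dt.date) -> TraitDescriptor:
    """Append a BBCH descriptor column for one calendar date.

    This realizes the start-of-session prompt that offers a growth-stage
    column for today: shortcut ``BBCH_<YYYY-MM-DD>``, one column per
    calendar date.
    """
    shortcut = f"BBCH_{date.isoformat()}"
    if any(d.shortcut == shortcut for d in book.descriptors):
        raise AlreadyExistsError(f"a BBCH descriptor for {date.isoformat()} already exists")
    descriptor = TraitDescriptor(
        shortcut=shortcut,
        description=f"BBCH growth stage recorded {date.isoformat()}",
        trait_type=TraitType.BBCH,
        selected=True,
    )
    book.add_descriptor(descriptor)
    if book.cursor.at_end:
        # new selectable column re-opens the pass
        book.cursor = Cursor(book.cursor.location_index, shortcut, book.cursor.direction)
    return descriptor


def set_selection(book: FieldBook, shortcuts: Iterable[str]) -> FieldBook:
    """Mark exactly the given descriptors for acquisition.

    Unselected descriptors are skipped by every traversal. If the
    cursor's descriptor is deselected, the cursor moves to the nearest
    selected descriptor at the same location (scanning forward through
    the descriptor list, wrapping once).
    """
    wanted = set(shortcuts)
    if not wanted:
        raise PhenoValidationError("selection must keep at least one descriptor")
    known = {d.shortcut for d in book.descriptors}
    unknown = wanted - known
    if unknown:
        raise UnknownShortcutError(
            f"unknown descriptor shortcut(s): {', '.join(sorted(unknown))}"
        )
    for d in book.descriptors:
        d.selected = d.shortcut in wanted
    cur = book.cursor
    if not cur.at_end and cur.descriptor_shortcut not in wanted:
        order = [d.shortcut for d in book.descriptors]
        start = order.index(cur.descriptor_shortcut)
        for step in range(1, len(order) + 1):
            candidate = order[(start + step) % len(order)]
            if candidate in wanted:
                book.cursor = Cursor(cur.location_index, candidate, cur.direction)
                break
    return book


def goto_location(
    book: FieldBook,
    plot: str = "",
    row: str = "",
    plant: str = "",
    accession_name: str = "",
) -> Cursor:
    """Move the cursor to a directly addressed location."""
    for i, loc in enumerate(book.locations):
        if plot and row and plant:
            if loc.uses_triple_key and loc.key == (plot.strip(), row.strip(), plant.strip()):
                book.cursor = navigation.goto(book, i)
                return book.cursor
        elif accession_name and loc.accession_name.strip() == accession_name.strip():
            book.cursor = navigation.goto(book, i)
            return book.cursor
    raise UnknownLocationError(
        f"no location matches plot={plot!r} row={row!r} plant={plant!r} "
        f"accession={accession_name!r}"
    )
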