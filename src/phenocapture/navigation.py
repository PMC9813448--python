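"""Traversal and cursor movement over the field-book grid.

Canonical order walks plot → row → plant with numeric-aware label
comparison (plant "2" before plant "10"). Zigzag (serpentine) order
alternates the plant direction on consecutive rows of a plot, entering
each new row from the end where the previous row finished — the walking
pattern used to avoid dead-heading back to the row start in the field.
Alternative-key records (accession-name only) have no grid position; they
form one pseudo-row appended after all triple-key records.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import List, Optional

from .model import Cursor, FieldBook, LocationRecord


def numeric_key(label: str):
    """Sort key: all-digit labels compare numerically, others
    lexicographically after every number."""
    label = label.strip()
    if label.isdigit():
        return (0, int(label), "")
    return (1, 0, label)


def location_sort_key(record: LocationRecord):
    return (
        numeric_key(record.plot),
        numeric_key(record.row),
        numeric_key(record.plant),
    )


def canonical_order(locations: List[LocationRecord]) -> List[int]:
    """Indices sorted by plot, then row, then plant; alternative-key
    records keep input order and come last."""
    triple = [i for i, rec in enumerate(locations) if rec.uses_triple_key]
    alt = [i for i, rec in enumerate(locations) if not rec.uses_triple_key]
    triple.sort(key=lambda i: location_sort_key(locations[i]))
    return triple + alt


def rows_layout(locations: List[LocationRecord]) -> List[List[int]]:
    """The grid as a list of rows: triple-key rows grouped by (plot, row)
    in canonical order, plants sorted within each row, then one
    pseudo-row with all alternative-key records."""
    order = canonical_order(locations)
    triple = [i for i in order if locations[i].uses_triple_key]
    alt = [i for i in order if not locations[i].uses_triple_key]
    rows = [
        list(group)
        for _, group in groupby(
            triple, key=lambda i: (locations[i].plot.strip(), locations[i].row.strip())
        )
    ]
    if alt:
        rows.append(alt)
    return rows


@dataclass
class TraversalPlan:
    """A visiting order over all locations: a permutation of the indices."""

    sequence: List[int]
    mode: str = "standard"

    def position(self, location_index: int) -> int:
        return self.sequence.index(location_index)


def standard_plan(locations: List[LocationRecord]) -> TraversalPlan:
    return TraversalPlan(canonical_order(locations), mode="standard")


def zigzag_order(locations: List[LocationRecord], carry: bool = False) -> TraversalPlan:
    """Serpentine plan: within each plot rows stay in canonical order but
    the plant direction alternates, starting forward on the plot's first
    row. With ``carry`` the alternation continues across plot boundaries
    instead of resetting."""
    order = canonical_order(locations)
    triple = [i for i in order if locations[i].uses_triple_key]
    alt = [i for i in order if not locations[i].uses_triple_key]

    sequence: List[int] = []
    forward = True
    for plot, plot_group in groupby(triple, key=lambda i: locations[i].plot.strip()):
        if not carry:
            forward = True
        for _, row_group in groupby(
            plot_group, key=lambda i: locations[i].row.strip()
        ):
            row = list(row_group)
            sequence.extend(row if forward else reversed(row))
            forward = not forward
    sequence.extend(alt)  # pseudo-row, walked forward
    return TraversalPlan(sequence, mode="zigzag")


def traversal_plan(book: FieldBook) -> TraversalPlan:
    if book.options.zigzag:
        return zigzag_order(book.locations, carry=book.options.zigzag_carry)
    return standard_plan(book.locations)


# -- cursor movement ---------------------------------------------------------


def advance(book: FieldBook) -> Cursor:
    """Next selected descriptor at the same location; when the descriptor
    list is exhausted, the first selected descriptor at the next location
    of the active traversal plan; past the last cell, the end-state."""
    cur = book.cursor
    if cur.at_end:
        return cur.copy()
    selected = book.selected_descriptors
    shortcuts = [d.shortcut for d in selected]
    pos = shortcuts.index(cur.descriptor_shortcut)
    if pos + 1 < len(shortcuts):
        return Cursor(cur.location_index, shortcuts[pos + 1], cur.direction)
    plan = traversal_plan(book)
    plan_pos = plan.position(cur.location_index)
    if plan_pos + 1 < len(plan.sequence):
        return Cursor(plan.sequence[plan_pos + 1], shortcuts[0], cur.direction)
    return Cursor(cur.location_index, cur.descriptor_shortcut, cur.direction, at_end=True)


def retreat(book: FieldBook) -> Cursor:
    """Inverse of advance, clamped at the first cell of the plan."""
    cur = book.cursor
    selected = book.selected_descriptors
    shortcuts = [d.shortcut for d in selected]
    if cur.at_end:
        return Cursor(cur.location_index, shortcuts[-1], cur.direction)
    pos = shortcuts.index(cur.descriptor_shortcut)
    if pos > 0:
        return Cursor(cur.location_index, shortcuts[pos - 1], cur.direction)
    plan = traversal_plan(book)
    plan_pos = plan.position(cur.location_index)
    if plan_pos > 0:
        return Cursor(plan.sequence[plan_pos - 1], shortcuts[-1], cur.direction)
    return cur.copy()


def cell_sequence(book: FieldBook) -> List[tuple]:
    """All (location index, shortcut) cells in plan order."""
    plan = traversal_plan(book)
    shortcuts = [d.shortcut for d in book.selected_descriptors]
    return [(i, s) for i in plan.sequence for s in shortcuts]


def first_empty(book: FieldBook) -> Optional[Cursor]:
    """The first unrecorded (location, selected-descriptor) cell scanning
    forward from the cursor in plan order, wrapping once past the start;
    None when the book is complete. The current cell counts — an empty
    cursor cell returns the cursor itself."""
    cells = cell_sequence(book)
    if not cells:
        return None
    cur = book.cursor
    if cur.at_end:
        start = 0
    else:
        start = cells.index((cur.location_index, cur.descriptor_shortcut))
    for step in range(len(cells)):
        loc, shortcut = cells[(start + step) % len(cells)]
        if (loc, shortcut) not in book.observations:
            return Cursor(loc, shortcut, cur.direction)
    return None


def jump(book: FieldBook, direction: str) -> Cursor:
    """Directional location jump, descriptor unchanged.

    up/down move one plant within the current row, clamped at the row
    ends; left/right move to the adjacent row at the same plant position
    (matched by plant label when present, else the nearest position),
    clamped at the first and last row.
    """
    if direction not in ("up", "down", "left", "right"):
        raise ValueError(f"unknown jump direction {direction!r}")
    cur = book.cursor
    rows = rows_layout(book.locations)
    row_idx = plant_idx = None
    for r, row in enumerate(rows):
        if cur.location_index in row:
            row_idx, plant_idx = r, row.index(cur.location_index)
            break
    if row_idx is None:
        return cur.copy()

    if direction in ("up", "down"):
        delta = 1 if direction == "down" else -1
        new_plant = min(max(plant_idx + delta, 0), len(rows[row_idx]) - 1)
        target = rows[row_idx][new_plant]
    else:
        delta = 1 if direction == "right" else -1
        new_row = min(max(row_idx + delta, 0), len(rows) - 1)
        row = rows[new_row]
        label = book.locations[cur.location_index].plant.strip()
        labels = [book.locations[i].plant.strip() for i in row]
        if label and label in labels:
            target = row[labels.index(label)]
        else:
            target = row[min(plant_idx, len(row) - 1)]
    return Cursor(target, cur.descriptor_shortcut, cur.direction)


def goto(book: FieldBook, location_index: int) -> Cursor:
    """Cursor at a specific location, first selected descriptor."""
    selected = book.selected_descriptors
    return Cursor(location_index, selected[0].shortcut, book.cursor.direction)
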