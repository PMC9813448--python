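"""Traversal order, cursor advancement, first-empty search, arrow jumps."""

import random

import pytest
from hypothesis import given, strategies as st

from phenocapture import FieldBook, LocationRecord, Options, TraitDescriptor, TraitType
from phenocapture.navigation import (
    advance,
    canonical_order,
    cell_sequence,
    first_empty,
    jump,
    retreat,
    standard_plan,
    zigzag_order,
)


def grid_records(plots, rows_per_plot, plants):
    """plants: int, or {(plot, row): count} for ragged layouts."""
    records = []
    for p in range(1, plots + 1):
        for r in range(1, rows_per_plot + 1):
            n = plants if isinstance(plants, int) else plants[(p, r)]
            for q in range(1, n + 1):
                records.append(LocationRecord(plot=str(p), row=str(r), plant=str(q)))
    return records


def make_book(records, n_desc=2, **options):
    descriptors = [
        TraitDescriptor(shortcut=f"T{k}", trait_type=TraitType.TEXT)
        for k in range(1, n_desc + 1)
    ]
    book = FieldBook(locations=records, descriptors=descriptors, options=Options(**options))
    book.reset_cursor()
    return book


def serpentine_oracle(locations):
    """Independent brute-force serpentine enumeration: reverse every
    second row within a plot; alternative-key records last."""

    def k(s):
        s = s.strip()
        return (0, int(s), "") if s.isdigit() else (1, 0, s)

    triple = [
        i for i, rec in enumerate(locations)
        if rec.plot.strip() and rec.row.strip() and rec.plant.strip()
    ]
    alt = [i for i in range(len(locations)) if i not in triple]
    order = []
    for plot in sorted({locations[i].plot.strip() for i in triple}, key=k):
        in_plot = [i for i in triple if locations[i].plot.strip() == plot]
        rows = sorted({locations[i].row.strip() for i in in_plot}, key=k)
        for rank, row in enumerate(rows):
            members = sorted(
                (i for i in in_plot if locations[i].row.strip() == row),
                key=lambda i: k(locations[i].plant.strip()),
            )
            order.extend(members if rank % 2 == 0 else members[::-1])
    return order + alt


@st.composite
def fuzzed_grids(draw):
    plots = draw(st.integers(1, 4))
    records = []
    for p in range(1, plots + 1):
        for r in range(1, draw(st.integers(1, 5)) + 1):
            for q in range(1, draw(st.integers(1, 8)) + 1):
                records.append(LocationRecord(plot=str(p), row=str(r), plant=str(q)))
    return records


class TestCanonicalOrder:
    def test_plot_row_plant_sort(self):
        records = grid_records(2, 1, 2)
        random.Random(3).shuffle(records)
        ordered = [records[i].key for i in canonical_order(records)]
        assert ordered == [("1", "1", "1"), ("1", "1", "2"), ("2", "1", "1"), ("2", "1", "2")]

    def test_numeric_aware_plant_labels(self):
        records = [
            LocationRecord(plot="1", row="1", plant="10"),
            LocationRecord(plot="1", row="1", plant="2"),
        ]
        assert canonical_order(records) == [1, 0]

    def test_singleton(self):
        assert canonical_order([LocationRecord(plot="1", row="1", plant="1")]) == [0]

    def test_alternative_key_records_keep_input_order_after_grid(self):
        records = [
            LocationRecord(accession_name="B"),
            LocationRecord(plot="1", row="1", plant="1"),
            LocationRecord(accession_name="A"),
        ]
        assert canonical_order(records) == [1, 0, 2]


class TestZigzagOrder:
    def test_second_row_counts_backwards(self):
        records = grid_records(1, 2, 3)
        plan = zigzag_order(records)
        keys = [records[i].key for i in plan.sequence]
        assert keys == [
            ("1", "1", "1"), ("1", "1", "2"), ("1", "1", "3"),
            ("1", "2", "3"), ("1", "2", "2"), ("1", "2", "1"),
        ]

    def test_single_row_equals_canonical(self):
        records = grid_records(1, 1, 4)
        assert zigzag_order(records).sequence == canonical_order(records)

    def test_direction_resets_at_each_plot(self):
        records = grid_records(2, 2, 2)
        keys = [records[i].key for i in zigzag_order(records).sequence]
        # both plots start their first row forward
        assert keys[0] == ("1", "1", "1")
        assert keys[4] == ("2", "1", "1")

    def test_carry_continues_across_plots(self):
        records = grid_records(2, 1, 2)
        keys = [records[i].key for i in zigzag_order(records, carry=True).sequence]
        assert keys == [("1", "1", "1"), ("1", "1", "2"), ("2", "1", "2"), ("2", "1", "1")]

    @given(records=fuzzed_grids())
    def test_matches_brute_force_oracle(self, records):
        plan = zigzag_order(records)
        assert plan.sequence == serpentine_oracle(records)
        assert sorted(plan.sequence) == list(range(len(records)))

    @given(records=fuzzed_grids())
    def test_both_orders_are_permutations(self, records):
        assert sorted(canonical_order(records)) == list(range(len(records)))
        assert sorted(zigzag_order(records).sequence) == list(range(len(records)))

    def test_ragged_grid_against_oracle(self):
        records = grid_records(2, 2, {(1, 1): 3, (1, 2): 1, (2, 1): 2, (2, 2): 4})
        assert zigzag_order(records).sequence == serpentine_oracle(records)


class TestAdvance:
    def test_next_descriptor_same_location(self):
        book = make_book(grid_records(1, 1, 2), n_desc=2)
        cur = advance(book)
        assert (cur.location_index, cur.descriptor_shortcut) == (book.cursor.location_index, "T2")

    def test_end_state_after_last_cell(self):
        book = make_book(grid_records(1, 1, 1), n_desc=1)
        book.cursor = advance(book)
        assert book.cursor.at_end
        assert advance(book).at_end  # absorbing

    def test_skips_unselected_descriptors(self):
        book = make_book(grid_records(1, 1, 1), n_desc=5)
        for d in book.descriptors:
            d.selected = d.shortcut in ("T2", "T4")
        book.reset_cursor()
        assert book.cursor.descriptor_shortcut == "T2"
        assert advance(book).descriptor_shortcut == "T4"

    @pytest.mark.parametrize("zigzag", [False, True])
    def test_full_pass_visits_every_cell_exactly_once(self, zigzag):
        book = make_book(grid_records(2, 3, 4), n_desc=3, zigzag=zigzag)
        visited = []
        while not book.cursor.at_end:
            visited.append((book.cursor.location_index, book.cursor.descriptor_shortcut))
            book.cursor = advance(book)
        assert len(visited) == 24 * 3
        assert len(set(visited)) == len(visited)

    def test_retreat_inverts_advance(self):
        book = make_book(grid_records(1, 2, 2), n_desc=2, zigzag=True)
        start = (book.cursor.location_index, book.cursor.descriptor_shortcut)
        for _ in range(5):
            book.cursor = advance(book)
        for _ in range(5):
            book.cursor = retreat(book)
        assert (book.cursor.location_index, book.cursor.descriptor_shortcut) == start
        book.cursor = retreat(book)  # clamped at the first cell
        assert (book.cursor.location_index, book.cursor.descriptor_shortcut) == start


class TestFirstEmpty:
    def test_empty_book_returns_current_cell(self):
        book = make_book(grid_records(1, 1, 3))
        hit = first_empty(book)
        assert (hit.location_index, hit.descriptor_shortcut) == (
            book.cursor.location_index, book.cursor.descriptor_shortcut,
        )

    def test_complete_book_returns_none(self, tiny_book):
        from phenocapture import fill_fieldbook

        fill_fieldbook(tiny_book, 1.0, 0)
        assert first_empty(tiny_book) is None

    @pytest.mark.parametrize("zigzag", [False, True])
    def test_single_hole_is_found_from_any_cursor(self, zigzag):
        rng = random.Random(11)
        book = make_book(grid_records(2, 2, 3), n_desc=3, zigzag=zigzag)
        cells = cell_sequence(book)
        from phenocapture.model import Observation, TraitType as TT

        for _ in range(100):
            book.observations = {cell: Observation(TT.TEXT, "x") for cell in cells}
            hole = rng.choice(cells)
            del book.observations[hole]
            start = rng.choice(cells)
            book.cursor.location_index, book.cursor.descriptor_shortcut = start
            hit = first_empty(book)
            assert (hit.location_index, hit.descriptor_shortcut) == hole

    def test_wraps_once_past_the_start(self):
        book = make_book(grid_records(1, 1, 3), n_desc=1)
        cells = cell_sequence(book)
        from phenocapture.model import Observation, TraitType as TT

        book.observations = {cell: Observation(TT.TEXT, "x") for cell in cells[1:]}
        book.cursor.location_index = cells[-1][0]
        hit = first_empty(book)
        assert hit.location_index == cells[0][0]


class TestJump:
    def test_up_down_clamp_at_row_ends(self):
        book = make_book(grid_records(1, 1, 3))
        book.cursor = jump(book, "down")  # p1 -> p2
        book.cursor = jump(book, "down")  # p2 -> p3
        assert book.current_location().plant == "3"
        assert jump(book, "down").location_index == book.cursor.location_index

    def test_left_right_keep_plant_position(self):
        book = make_book(grid_records(1, 2, 3))
        book.cursor = jump(book, "down")  # (r1, p2)
        cur = jump(book, "right")
        assert book.locations[cur.location_index].key == ("1", "2", "2")

    def test_right_into_shorter_row_takes_nearest_plant(self):
        records = grid_records(1, 2, {(1, 1): 3, (1, 2): 2})
        book = make_book(records)
        book.cursor = jump(book, "down")
        book.cursor = jump(book, "down")  # (r1, p3)
        cur = jump(book, "right")
        assert book.locations[cur.location_index].key == ("1", "2", "2")

    def test_descriptor_unchanged(self):
        book = make_book(grid_records(1, 2, 2), n_desc=3)
        book.cursor = advance(book)
        shortcut = book.cursor.descriptor_shortcut
        assert jump(book, "right").descriptor_shortcut == shortcut

    def test_left_clamps_at_first_row(self):
        book = make_book(grid_records(1, 2, 2))
        assert jump(book, "left").location_index == book.cursor.location_index


def test_standard_plan_follows_canonical_order():
    records = grid_records(2, 2, 2)
    random.Random(1).shuffle(records)
    assert standard_plan(records).sequence == canonical_order(records)
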