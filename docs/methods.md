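# Methods

This note documents the data model, the behavioural rules the engine
implements, the synthetic-data generator, and the design choices made
where the behaviour of a field-capture tool is genuinely open.

## Field-book model

A field book is a session over an ordered list of plant locations and an
ordered list of trait descriptors, with a sparse observation matrix
keyed by (location index, descriptor shortcut). Locations carry eleven
passport columns in fixed order (plot, row, plant, accession name,
accession number, variety number, genotype, mother, father, information,
database-key). Validity follows the obligatory-column rule: a record
needs either a complete (plot, row, plant) triple or, alternatively, a
non-empty accession name. The database-key is never shown in listings
but is always copied verbatim into the output, so a downstream database
can re-join exported rows without guessing.

Triple keys must be unique within a book. A duplicate triple on import
is reported (with its row number) and the second occurrence rejected,
like any other invalid row; import only aborts when *no* valid location
remains. Trailing fully empty spreadsheet rows are skipped silently.

## Trait types and validation

Five descriptor type codes exist (1 rating, 2 measured value, 3 date,
4 text, 5 BBCH); anything else aborts the import naming the offending
row — silently dropping a column would corrupt downstream ingestion.

Rating scales live in the descriptor's values column as
`code: label; code: label; …` — entries split on `;`, code split from
label at the first `:`, all tokens trimmed, order preserved. Codes are
arbitrary text tokens (UPOV-style letter scales are legal), must be
unique, and may not contain `,`, which is reserved as the
multiple-selection list separator. By default a rating outside the scale
is rejected; `Options.strict_scale=False` stores off-scale tokens as-is
for users who want the permissive behaviour.

Measured values accept `.` as the only decimal separator (again because
`,` separates list values) and must be finite. Dates parse from ISO-8601
plus the common `DD.MM.YYYY` / `DD/MM/YYYY` spreadsheet forms, and from
native spreadsheet date cells. Text accepts anything. BBCH entries are
validated against the scale registry; a bare two-digit code uses the
session's sticky species context, a `species:code` entry overrides it.

`validate_value` is total: every input yields either a typed Observation
or a typed validation error. `record` is atomic — on a validation error
the matrix, remarks and cursor are untouched. Re-recording a filled cell
overwrites it and appends an audit line; overwrite-with-audit is the
safest rule for correcting scores in the field.

## BBCH scales

A scale has exactly three levels: species → principal growth stage
(single digit) → specific growth stage (two digits whose first digit is
the parent principal stage). Codes are stored as zero-padded two-digit
text, never integers; one-digit and three-digit (mezzo) forms are
rejected. The template workbook puts the species name and the principal
stages on the first sheet and one principal stage's specific stages on
each further sheet; sheets bind to principal stages in order, and a
sheet named with a principal digit overrides the order. Sample images
bind to principal stages by filename stem, case-insensitively.

Importing a template adds the scale to the registry and moves the
consumed file into a `processed/` subfolder — consume-on-import keeps the
drop-folder workflow, but a library should not destroy user files, so it
moves rather than deletes. The registry persists one template-format
workbook per species under `bbch/`, i.e. the on-disk form is the same
format a user would author.

The bundled scales for the seven stock crops (apple, cereals, grapevine,
maize, potato, rapeseed, rice) are deterministic synthetic stand-ins,
flagged by the `-fixture` suffix in their species names: structurally
valid hierarchies (principal stages 0–8, specifics {d0, d1, d3, d5, d7})
for tests and demos, not transcriptions of the official BBCH monograph.
Real scales are imported via the template path.

## Traversal

Canonical order sorts by plot, then row, then plant, comparing all-digit
labels numerically (plant "2" before "10") and everything else
lexicographically. Zigzag (serpentine) order keeps rows in canonical
order but alternates the plant direction on consecutive rows of a plot,
starting forward on each plot's first row; `Options.zigzag_carry`
exposes the alternative of carrying the alternation across plot
boundaries. Accession-only records have no grid position: they form a
single pseudo-row appended after all triple-key records and are walked
forward.

The cursor advances descriptor-first: next selected descriptor at the
same location, then the first selected descriptor of the next location
in the active plan; past the last cell it reaches an explicit end-state
value. Unselected descriptors are skipped everywhere (partial
selection). First-empty scans (location × selected descriptor) cells
forward from the cursor in plan order, wrapping once; the current cell
counts, and a complete book yields "none". Arrow jumps clamp at grid
edges rather than wrapping — mirroring physical walking — and
left/right matches the plant label in the adjacent row when present,
else the nearest position; rows may be ragged, and traversal follows
actual membership, never a padded rectangle.

## Files

The input workbook has Locations first and Traits second; sheets named
"Locations"/"Traits" are honoured wherever they sit, otherwise position
decides. The first row of each sheet is a header; unexpected header
strings warn but parsing stays positional, and the single merged
"accession name and number" column variant is accepted on read (the
merged value lands in accession name). Accepted containers are .xlsx and
a CSV pair (`<name>_locations.csv` + `<name>_traits.csv`); legacy .xls
input raises a clear unsupported-format error — modern spreadsheet tools
write xlsx, and keeping one reader keeps the format contract testable.

The output table is: all eleven location columns verbatim, the two
remark columns (location info, plant note — always separate), then one
column per descriptor, one row per location in book order. XLSX stores
measured values and dates as native typed cells; CSV uses ISO-8601
dates, `repr`-minimal decimals, comma delimiter, double-quote quoting,
UTF-8 and LF. Multi-valued ratings join with `,`; BBCH cells serialize
as `species:code` so mixed-species books round-trip unambiguously
through text. `read_output` restores a session from an output file,
re-validating every cell; failures are collected in a report with the
offending value retained, never dropped silently. One caveat: an empty
text observation serializes to an empty cell and is therefore
indistinguishable from "unrecorded"; the generator never produces empty
text values, and real sessions record *something* or nothing.

## Sessions and the CLI

The CLI persists a versioned JSON snapshot of the book; a schema-version
mismatch refuses to load. The dump is canonical (sorted keys, sorted
cells), so identical sessions have identical bytes. Every state-changing
command goes through one dispatcher and is appended to a JSONL command
log; `replay` re-executes a log into a fresh session file, and
byte-equality of the two session files is the replay-determinism check.
Exit codes separate validation failures (2) from I/O failures (3).

Photo names are `<plot>-<row>-<plant>_<YYYYMMDD-HHMMSS>[_<variety>]`,
with the accession name standing in as the variety part (the schema has
no separate variety-name column) and as the location part for
accession-only records. Names are sanitized (spaces → `-`, reserved
characters stripped) and use local time — field devices are set to local
time, and the stamp only needs to sort and be unique per location and
second.

The dated-BBCH convenience (`add-bbch`, or the opt-in question at
`init`) appends one type-5 column per calendar date, shortcut
`BBCH_<YYYY-MM-DD>` — one column per date, since a phenology run scores
each plant once per visit.

## Synthetic data

`FixtureSpec` generates trials with configurable plot/row/plant counts
(ragged layouts allowed), a descriptor mix over the five types, a fill
fraction and a seed. All content flows from one seeded generator and the
xlsx zip metadata is rewritten with constant timestamps, so the same
spec and seed give byte-identical files. Generated passport fields are
plausible German grapevine-breeding names; type-1 descriptors all carry
the canonical nine-point example scale; filled cells always pass
validation for their type.

What the generator does *not* emulate: real passport data quality
(missing fields, encoding noise, duplicated accessions), heterogeneous
header conventions, observer error distributions, or agronomically
meaningful trait values. Passing tests therefore demonstrate the format
and behaviour contract — parsing, validation, traversal, round-trips —
not robustness to arbitrarily messy real-world spreadsheets.

## Problem sizes used in checks

The test suite and the acceptance script exercise: 200 (suite) / 60
(script) fuzzed field books up to 10×10×10 locations (resampled to ≤ 300
locations, plus one pinned 10×10×10 case) and up to 20 descriptors with
fill 0–1, round-tripped through both formats; 500 fuzzed, possibly
ragged grids against an independently coded serpentine enumeration; 100
single-hole placements for the first-empty search; 30 fuzzed BBCH scales
with exhaustive acceptance over all 100 two-digit codes; and a scripted
50-command CLI session replayed from its log. These sizes give each
property ample room to fail while keeping a full run fast enough to be
part of everyday development.

## Known limitations

- No legacy .xls reading, no streaming for very large workbooks, no
  formula evaluation or cell styling.
- No ontology mapping of descriptors (Crop Ontology / AGROVOC) and no
  multi-user conflict resolution; the command log is an audit trail, not
  a merge tool.
- Only two-digit BBCH codes; mezzo (three-digit) stages are rejected.
- The undo story is single-cell overwrite logging, not a full undo stack.
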