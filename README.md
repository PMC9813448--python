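# phenocapture

A scriptable field-book engine for manual plant phenotyping. It targets
the people who still walk trials with a clipboard — genebank curators
characterizing accessions, breeders scoring nurseries, researchers doing
phenology runs — and gives them (and their pipelines) a library and CLI
that covers the full data-capture loop without a GUI: define descriptors,
load a plant list, walk the field in the order you actually walk it,
validate every entry as it is typed, and export a table a spreadsheet or
LIMS can ingest directly.

## The model

A session (**field book**) is:

- an ordered list of **locations** — plant positions keyed by
  *(plot, row, plant)*, plus passport columns (accession name/number,
  variety number, genotype, mother, father, information, and a hidden
  `database-key` that is passed through verbatim for database
  synchronization). A record may instead be keyed by accession name alone
  when no grid position exists.
- an ordered list of **trait descriptors**, each with a shortcut,
  description, type code, values string and remark. Five types exist:

  | code | type | entry |
  |------|------|-------|
  | 1 | rating | categorical score on a scale given in the values column, e.g. `1: none; 3: little; 5: medium; 7: strong; 9: very strong` |
  | 2 | measured value | decimal number (units in the remark) |
  | 3 | date | calendar date, with quick buttons for today ± 2 days |
  | 4 | text | free text |
  | 5 | BBCH | phenological growth stage from a registered BBCH scale |

- a sparse **observation matrix** over (location × descriptor), two
  per-location **remark** fields, and a **cursor**.

**BBCH scales** are three-level hierarchies — species → principal growth
stage (digit 0–9) → specific growth stage (two digits, first digit =
principal stage). New species are imported from a template workbook;
species and principal stage are carried forward between entries so only
the specific stage is picked per plant.

**Traversal** follows either canonical order (plot → row → plant,
numeric-aware) or **zigzag** (serpentine) order, which walks alternate
rows backwards so the next row is entered from the end where the last one
finished. The cursor auto-advances through the *selected* descriptors of
each location; a first-empty search jumps to the next unrecorded cell;
arrow jumps move within and across rows.

Input and output are plain workbooks: a two-sheet input file (Locations +
Traits, xlsx or a CSV pair) and an output table with one row per location
— all input columns verbatim, two remark columns, one column per
descriptor — as xlsx or CSV. Round-trips are lossless.

## Worked example

```bash
phenocapture fixtures make --plots 2 --rows 1 --plants 3 --seed 7 --out .
phenocapture init fixture_input.xlsx
#   loaded 6 locations, 5 descriptors
#   1 1 1 | RAT1
phenocapture record --value 5
#   recorded
#   1 1 1 | MEA1
phenocapture jump right
#   2 1 1 | MEA1
phenocapture remark --location-info "north edge" --plant-note "leaf damage"
#   remarks stored
phenocapture export --format csv --out out.csv
#   wrote out.csv
```

The cursor line is always `plot row plant | descriptor`: after recording
the rating `5` at plant (1, 1, 1) the cursor auto-advanced to that
plant's next descriptor (`MEA1`, a measured value), and `jump right`
moved to the same plant position in the next row — here the first row of
plot 2. The exported CSV contains the six location rows with all passport
columns, the two remark columns (`north edge` / `leaf damage` on the row
where they were entered) and one column per descriptor, with `5` in the
single recorded cell.

Every state-changing command is appended to a JSONL log next to the
session file; `phenocapture replay --log session.json.log --session
rebuilt.json` reproduces the session byte for byte.

The same engine is importable:

```python
from phenocapture import FixtureSpec, make_session, record, write_output

book, path = make_session(FixtureSpec(plots=2, plants_per_row=3, seed=7), ".")
record(book, "5")                    # validated against the 1-9 scale
write_output(book, "out.xlsx")
```

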