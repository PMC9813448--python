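"""Versioned session persistence.

A session file is a JSON snapshot of one field book: locations,
descriptors with their selection flags, the observation matrix, remarks,
options and cursor. Saving and re-loading round-trips to a structurally
identical book; a file written by a different schema version is refused
with a clear message. The dump is canonical (sorted keys, sorted
observation cells) so that identical sessions have identical bytes —
this is what makes command-log replay verifiable.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Optional, Tuple

from .bbch import BBCHRegistry
from .errors import PhenoIOError, SessionVersionError
from .model import (
    BBCHObservationCode,
    Cursor,
    FieldBook,
    LocationRecord,
    Observation,
    Options,
    Remarks,
    TraitDescriptor,
    TraitType,
)

SCHEMA_VERSION = 1


def _payload_to_json(obs: Observation):
    if obs.kind == TraitType.RATING:
        return list(obs.value)
    if obs.kind == TraitType.MEASURED:
        return obs.value
    if obs.kind == TraitType.DATE:
        return obs.value.isoformat()
    if obs.kind == TraitType.BBCH:
        return {"species": obs.value.species, "code": obs.value.code}
    return obs.value


def _payload_from_json(kind: TraitType, data):
    if kind == TraitType.RATING:
        return [str(tok) for tok in data]
    if kind == TraitType.MEASURED:
        return float(data)
    if kind == TraitType.DATE:
        return _dt.date.fromisoformat(data)
    if kind == TraitType.BBCH:
        return BBCHObservationCode(data["species"], data["code"])
    return str(data)


def fieldbook_to_dict(book: FieldBook, input_path: str = "") -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "input_path": str(input_path),
        "options": {
            "zigzag": book.options.zigzag,
            "multiple_selection": book.options.multiple_selection,
            "bbch_question": book.options.bbch_question,
            "strict_scale": book.options.strict_scale,
            "zigzag_carry": book.options.zigzag_carry,
        },
        "species_context": book.species_context,
        "cursor": {
            "location_index": book.cursor.location_index,
            "descriptor_shortcut": book.cursor.descriptor_shortcut,
            "direction": book.cursor.direction,
            "at_end": book.cursor.at_end,
        },
        "locations": [list(loc.as_row()) for loc in book.locations],
        "descriptors": [
            {
                "shortcut": d.shortcut,
                "description": d.description,
                "type": int(d.trait_type),
                "values": d.values_raw,
                "remark": d.remark,
                "selected": d.selected,
            }
            for d in book.descriptors
        ],
        "observations": [
            [i, shortcut, int(obs.kind), _payload_to_json(obs)]
            for (i, shortcut), obs in sorted(book.observations.items())
        ],
        "remarks": {
            str(i): {"location_info": r.location_info, "plant_note": r.plant_note}
            for i, r in sorted(book.remarks.items())
        },
        "audit_log": list(book.audit_log),
        "import_report": list(book.import_report),
    }


def fieldbook_from_dict(data: dict, registry: Optional[BBCHRegistry] = None) -> Tuple[FieldBook, str]:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SessionVersionError(
            f"session schema version {version!r} is not supported "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    opts = data.get("options", {})
    book = FieldBook(
        locations=[LocationRecord.from_row(row) for row in data["locations"]],
        descriptors=[
            TraitDescriptor(
                shortcut=d["shortcut"],
                description=d.get("description", ""),
                trait_type=TraitType(d["type"]),
                values_raw=d.get("values", ""),
                remark=d.get("remark", ""),
                selected=bool(d.get("selected", True)),
            )
            for d in data["descriptors"]
        ],
        options=Options(
            zigzag=bool(opts.get("zigzag", False)),
            multiple_selection=bool(opts.get("multiple_selection", False)),
            bbch_question=bool(opts.get("bbch_question", False)),
            strict_scale=bool(opts.get("strict_scale", True)),
            zigzag_carry=bool(opts.get("zigzag_carry", False)),
        ),
        registry=registry or BBCHRegistry.with_builtin(),
        species_context=data.get("species_context"),
        audit_log=list(data.get("audit_log", [])),
        import_report=list(data.get("import_report", [])),
    )
    for i, shortcut, kind, payload in data.get("observations", []):
        kind = TraitType(kind)
        book.observations[(int(i), shortcut)] = Observation(
            kind, _payload_from_json(kind, payload)
        )
    for key, r in data.get("remarks", {}).items():
        book.remarks[int(key)] = Remarks(
            r.get("location_info", ""), r.get("plant_note", "")
        )
    cur = data.get("cursor", {})
    book.cursor = Cursor(
        location_index=int(cur.get("location_index", 0)),
        descriptor_shortcut=cur.get("descriptor_shortcut", ""),
        direction=cur.get("direction", "forward"),
        at_end=bool(cur.get("at_end", False)),
    )
    return book, data.get("input_path", "")


def save_session(book: FieldBook, path, input_path: str = "") -> Path:
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                fieldbook_to_dict(book, input_path),
                fh,
                sort_keys=True,
                ensure_ascii=False,
                indent=1,
            )
            fh.write("\n")
    except OSError as exc:
        raise PhenoIOError(f"cannot write session {path}: {exc}") from exc
    return path


def load_session(path, registry: Optional[BBCHRegistry] = None) -> Tuple[FieldBook, str]:
    path = Path(path)
    if not path.exists():
        raise PhenoIOError(f"session file {path} does not exist (run init first)")
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return fieldbook_from_dict(data, registry=registry)
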