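"""BBCH growth-stage scales: registry, template import/export, code
validation and the sticky entry context.

A BBCH scale codes plant phenology in exactly three levels: species →
principal growth stage (one digit, 0–9) → specific growth stage (two
digits whose first digit is the parent principal stage). Scales for new
species are added through a template workbook: the first sheet names the
species and lists the principal stages (with optional sample-image names),
every further sheet lists the specific stages of one principal stage.

The bundled scales for the seven stock crops (apple, cereals, grapevine,
maize, potato, rapeseed, rice) are synthetic stand-ins generated in code:
structurally valid BBCH hierarchies for tests and demos, not
transcriptions of the official monograph — hence the ``-fixture`` suffix
in their species names.
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import (
    OrphanCodeError,
    TemplateFormatError,
    UnknownBBCHCodeError,
    UnknownSpeciesError,
)

#: The three hierarchy levels of every scale.
HIERARCHY_LEVELS = ("species", "principal growth stage", "specific growth stage")


def check_code_shape(code: str) -> str:
    """Specific codes are exactly two digits; no normalization of
    one-digit input ("7" is rejected, "07" accepted)."""
    code = str(code).strip()
    if not re.fullmatch(r"\d\d", code):
        raise UnknownBBCHCodeError(
            f"{code!r} is not a two-digit BBCH code (mezzo/other forms are not accepted)"
        )
    return code


@dataclass
class PrincipalStage:
    code: str  # single digit "0"-"9"
    title: str
    image_name: Optional[str] = None


@dataclass
class SpecificStage:
    code: str  # two digits, first digit = parent principal code
    description: str


@dataclass
class BBCHScale:
    """Three-level growth-stage hierarchy for one species."""

    species: str
    principal_stages: list = field(default_factory=list)
    specific_stages: dict = field(default_factory=dict)  # principal code -> [SpecificStage]

    def validate(self) -> None:
        if not self.species or not str(self.species).strip():
            raise TemplateFormatError("scale has an empty species name")
        seen_principal = set()
        for p in self.principal_stages:
            if not re.fullmatch(r"\d", p.code):
                raise TemplateFormatError(
                    f"principal stage code {p.code!r} is not a single digit"
                )
            if p.code in seen_principal:
                raise TemplateFormatError(f"duplicate principal stage {p.code!r}")
            seen_principal.add(p.code)
        seen_specific = set()
        for principal_code, stages in self.specific_stages.items():
            if principal_code not in seen_principal:
                raise OrphanCodeError(
                    f"specific stages listed under principal {principal_code!r} "
                    "which is not defined"
                )
            for s in stages:
                check_code_shape(s.code)
                if s.code[0] != principal_code:
                    raise OrphanCodeError(
                        f"specific code {s.code!r} does not belong to principal "
                        f"stage {principal_code!r}"
                    )
                if s.code in seen_specific:
                    raise TemplateFormatError(f"duplicate specific code {s.code!r}")
                seen_specific.add(s.code)

    def codes(self) -> set:
        return {s.code for stages in self.specific_stages.values() for s in stages}

    def principal(self, code: str) -> PrincipalStage:
        for p in self.principal_stages:
            if p.code == code:
                return p
        raise KeyError(code)

    def depth(self) -> int:
        """Number of hierarchy levels (always three: species, principal,
        specific)."""
        return len(HIERARCHY_LEVELS)


from .model import BBCHObservationCode  # noqa: E402  (shared value type)


class BBCHRegistry:
    """In-memory scale registry with optional directory persistence.

    Persisted as one template-format workbook per species under a
    ``bbch/`` data directory, so the on-disk form is the same format a
    user would author by hand.
    """

    def __init__(self, scales=()):
        self._scales = {}
        for scale in scales:
            self.add(scale)

    def add(self, scale: BBCHScale, replace: bool = True) -> None:
        scale.validate()
        if not replace and scale.species in self._scales:
            raise TemplateFormatError(f"species {scale.species!r} already registered")
        self._scales[scale.species] = scale

    def species(self) -> list:
        return sorted(self._scales)

    def get(self, species: str) -> BBCHScale:
        try:
            return self._scales[species]
        except KeyError:
            raise UnknownSpeciesError(
                f"species {species!r} is not in the BBCH registry "
                f"(known: {', '.join(self.species()) or 'none'})"
            )

    def __contains__(self, species: str) -> bool:
        return species in self._scales

    def validate_code(self, species: str, code: str) -> BBCHObservationCode:
        scale = self.get(species)
        code = check_code_shape(code)
        if code not in scale.codes():
            raise UnknownBBCHCodeError(
                f"code {code!r} is not a specific growth stage of {species!r}"
            )
        return BBCHObservationCode(species, code)

    # -- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for species, scale in self._scales.items():
            export_template(scale, directory / f"{_slug(species)}.xlsx")

    @classmethod
    def load(cls, directory, include_builtin: bool = True) -> "BBCHRegistry":
        registry = cls(builtin_fixture_scales() if include_builtin else ())
        directory = Path(directory)
        if directory.is_dir():
            for path in sorted(directory.glob("*.xlsx")):
                registry.add(parse_template(path))
        return registry

    @classmethod
    def with_builtin(cls) -> "BBCHRegistry":
        return cls(builtin_fixture_scales())


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", text.strip()) or "scale"


# -- sticky entry context ----------------------------------------------------


@dataclass(frozen=True)
class EntryContext:
    """Carried-forward species and principal stage for BBCH entry.

    Only the specific growth stage must be picked at every location; the
    upper two levels are copied from the previous entry unless overridden.
    """

    species: Optional[str] = None
    principal: Optional[str] = None


def sticky_context(
    previous: Optional[BBCHObservationCode],
    species: Optional[str] = None,
    principal: Optional[str] = None,
) -> EntryContext:
    ctx_species = species if species is not None else (previous.species if previous else None)
    ctx_principal = principal if principal is not None else (
        previous.code[0] if previous else None
    )
    return EntryContext(ctx_species, ctx_principal)


# -- template I/O ------------------------------------------------------------
#
# Layout:
#   sheet 1  — A1: species name; row 2: header (code, title, image);
#              rows 3+: one principal stage each.
#   sheet 2+ — one sheet per principal stage, bound by sheet order, or by
#              name when the sheet is named with the principal digit;
#              row 1: header (code, description); rows 2+: specific stages.


def parse_template(path) -> BBCHScale:
    """Read a template workbook into a validated scale (no side effects)."""
    from openpyxl import load_workbook

    from .errors import PhenoIOError

    path = Path(path)
    if not path.exists():
        raise PhenoIOError(f"template {path} does not exist")
    wb = load_workbook(path, data_only=True)
    sheets = wb.worksheets
    if len(sheets) < 2:
        raise TemplateFormatError(
            f"template {path.name} needs at least two sheets, found {len(sheets)}"
        )
    first = sheets[0]
    species = first.cell(row=1, column=1).value
    if species is None or not str(species).strip():
        raise TemplateFormatError(f"template {path.name}: empty species name in A1")
    species = str(species).strip()

    principals = []
    for cells in first.iter_rows(min_row=3, max_col=3, values_only=True):
        code, title, image = (list(cells) + [None, None, None])[:3]
        if code is None and title is None:
            continue
        code = str(code).strip() if code is not None else ""
        principals.append(
            PrincipalStage(
                code=code,
                title=str(title).strip() if title is not None else "",
                image_name=str(image).strip() if image not in (None, "") else None,
            )
        )
    scale = BBCHScale(species=species, principal_stages=principals)

    ordered_codes = [p.code for p in principals]
    unbound = list(ordered_codes)
    for sheet in sheets[1:]:
        name = str(sheet.title).strip()
        if re.fullmatch(r"\d", name):
            principal_code = name
            if principal_code not in ordered_codes:
                raise OrphanCodeError(
                    f"sheet {name!r} names principal stage {principal_code!r} "
                    "which the first sheet does not define"
                )
            if principal_code in unbound:
                unbound.remove(principal_code)
        else:
            if not unbound:
                raise TemplateFormatError(
                    f"sheet {sheet.title!r} has no principal stage left to bind to"
                )
            principal_code = unbound.pop(0)
        stages = []
        for cells in sheet.iter_rows(min_row=2, max_col=2, values_only=True):
            code, description = (list(cells) + [None, None])[:2]
            if code is None and description is None:
                continue
            code = str(code).strip() if code is not None else ""
            stages.append(
                SpecificStage(
                    code=code,
                    description=str(description).strip() if description is not None else "",
                )
            )
        if stages:
            scale.specific_stages.setdefault(principal_code, []).extend(stages)
    scale.validate()
    return scale


def export_template(scale: BBCHScale, path) -> Path:
    """Write a scale back out in template-workbook form."""
    from openpyxl import Workbook

    scale.validate()
    wb = Workbook()
    first = wb.active
    first.title = "Species"
    first.cell(row=1, column=1, value=scale.species)
    for col, header in enumerate(("code", "title", "image"), start=1):
        first.cell(row=2, column=col, value=header)
    for i, p in enumerate(scale.principal_stages, start=3):
        first.cell(row=i, column=1, value=p.code)
        first.cell(row=i, column=2, value=p.title)
        if p.image_name:
            first.cell(row=i, column=3, value=p.image_name)
    for p in scale.principal_stages:
        stages = scale.specific_stages.get(p.code, [])
        if not stages:
            continue
        ws = wb.create_sheet(title=p.code)
        ws.cell(row=1, column=1, value="code")
        ws.cell(row=1, column=2, value="description")
        for i, s in enumerate(stages, start=2):
            ws.cell(row=i, column=1, value=s.code)
            ws.cell(row=i, column=2, value=s.description)
    # constant document properties keep template bytes reproducible
    import datetime as _dt

    wb.properties.created = _dt.datetime(2000, 1, 1)
    wb.properties.modified = _dt.datetime(2000, 1, 1)
    wb.properties.creator = "phenocapture"
    wb.properties.lastModifiedBy = "phenocapture"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wb.save(path)
    return path


IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".gif", ".bmp", ".webp")


def associate_images(scale: BBCHScale, folder) -> int:
    """Bind sample images to principal stages by filename.

    A sibling image file whose stem equals a principal-stage title
    (case-insensitive) becomes that stage's sample image. Returns the
    number of stages bound.
    """
    folder = Path(folder)
    if not folder.is_dir():
        return 0
    by_stem = {}
    for item in folder.iterdir():
        if item.is_file() and item.suffix.lower() in IMAGE_EXTENSIONS:
            by_stem.setdefault(item.stem.casefold(), item.name)
    bound = 0
    for p in scale.principal_stages:
        hit = by_stem.get(p.title.casefold())
        if hit is not None:
            p.image_name = hit
            bound += 1
    return bound


def import_template(path, registry: Optional[BBCHRegistry] = None, consume: bool = True):
    """Import a template into the registry.

    Parses and validates the template, binds any sibling stage images,
    adds the scale to ``registry`` (when given) and — mirroring the app's
    consume-on-import behaviour, but non-destructively — moves the
    template file into a ``processed/`` subfolder next to it.
    """
    path = Path(path)
    scale = parse_template(path)
    associate_images(scale, path.parent)
    if registry is not None:
        registry.add(scale)
    if consume:
        processed = path.parent / "processed"
        processed.mkdir(exist_ok=True)
        shutil.move(str(path), str(processed / path.name))
    return scale


# -- bundled synthetic scales ------------------------------------------------

FIXTURE_CROPS = ("apple", "cereals", "grapevine", "maize", "potato", "rapeseed", "rice")

_STAGE_TITLES = (
    "germination and bud development",
    "leaf development",
    "formation of side shoots",
    "stem elongation",
    "development of harvestable parts",
    "inflorescence emergence",
    "flowering",
    "development of fruit",
    "ripening",
)

# second digits used for every principal stage of every fixture scale
_FIXTURE_SECOND_DIGITS = ("0", "1", "3", "5", "7")


def make_fixture_scale(crop: str) -> BBCHScale:
    """Deterministic synthetic scale for one crop: principal stages 0-8,
    specific stages {d0, d1, d3, d5, d7} under each."""
    species = f"{crop}-fixture"
    principals = [
        PrincipalStage(code=str(d), title=_STAGE_TITLES[d]) for d in range(9)
    ]
    specifics = {
        str(d): [
            SpecificStage(
                code=f"{d}{second}",
                description=f"{_STAGE_TITLES[d]}, step {second}",
            )
            for second in _FIXTURE_SECOND_DIGITS
        ]
        for d in range(9)
    }
    scale = BBCHScale(species=species, principal_stages=principals, specific_stages=specifics)
    scale.validate()
    return scale


def builtin_fixture_scales() -> list:
    return [make_fixture_scale(crop) for crop in FIXTURE_CROPS]
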