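"""Typed error hierarchy.

Two broad families matter to callers: validation failures (bad values,
malformed descriptors, schema violations — CLI exit code 2) and I/O
failures (unreadable or unwritable files — CLI exit code 3).
"""


class PhenoError(Exception):
    """Base class for all package errors."""


class PhenoValidationError(PhenoError):
    """A value, record or file violates the field-book contract."""


class PhenoIOError(PhenoError):
    """A file could not be read or written."""


# -- rating scales -----------------------------------------------------------

class MissingScaleError(PhenoValidationError):
    """A rating descriptor has an empty values column."""


class DuplicateScaleCodeError(PhenoValidationError):
    """Two entries of one rating scale share a code."""


class MalformedScaleEntryError(PhenoValidationError):
    """A scale entry lacks the ``code: label`` form."""


# -- descriptors & values ----------------------------------------------------

class UnknownTraitTypeError(PhenoValidationError):
    """Trait type code outside 1–5."""


class DuplicateShortcutError(PhenoValidationError):
    """Two descriptors share a shortcut within one field book."""


class OutOfScaleError(PhenoValidationError):
    """A rating token is not a member of the descriptor's scale."""


class NonNumericValueError(PhenoValidationError):
    """A measured-value entry failed to parse as a decimal number."""


class UnparseableDateError(PhenoValidationError):
    """A date entry failed to parse."""


class MultipleNotAllowedError(PhenoValidationError):
    """Comma-separated rating tokens while multiple selection is off."""


# -- locations ---------------------------------------------------------------

class InvalidLocationError(PhenoValidationError):
    """A location row satisfies neither the triple-key nor the
    accession-name rule."""


class UnknownLocationError(PhenoValidationError):
    """An address does not match any location in the book."""


class UnknownShortcutError(PhenoValidationError):
    """A descriptor shortcut does not exist in the book."""


# -- BBCH --------------------------------------------------------------------

class UnknownSpeciesError(PhenoValidationError):
    """Species absent from the BBCH registry."""


class UnknownBBCHCodeError(PhenoValidationError):
    """Two-digit code absent from the species' scale."""


class OrphanCodeError(PhenoValidationError):
    """A specific growth stage whose leading digit has no principal stage."""


class TemplateFormatError(PhenoValidationError):
    """A BBCH template workbook violates the template layout."""


# -- workbooks & sessions ----------------------------------------------------

class MissingSheetError(PhenoValidationError):
    """Input workbook lacks the Locations or Traits sheet."""


class NoValidLocationsError(PhenoValidationError):
    """No row of the Locations sheet yielded a valid record."""


class ColumnMismatchError(PhenoValidationError):
    """Output file columns do not match the field book's descriptors."""


class SessionVersionError(PhenoValidationError):
    """Session file written by an incompatible schema version."""


class AlreadyExistsError(PhenoValidationError):
    """Attempt to create an entity that already exists (e.g. a dated
    BBCH descriptor for the same calendar date)."""
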