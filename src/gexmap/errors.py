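"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`GexmapError` so the CLI can
distinguish user errors (exit code 1) from internal bugs (exit code 2).
"""

from __future__ import annotations


class GexmapError(Exception):
    """Base class for all errors raised by gexmap."""


class FormatError(GexmapError):
    """An input file does not have the expected structure (e.g. a missing
    required column or an unreadable header)."""


class ParseError(GexmapError):
    """A value inside an otherwise well-formed file could not be parsed;
    the message names the file, the line and the offending value."""


class IntegrityError(GexmapError):
    """A uniqueness or consistency constraint was violated (duplicate gene
    in one quantification file, duplicate sample label in a cohort, ...)."""


class ValidationError(GexmapError):
    """A parameter, record or configuration violates a documented invariant."""


class UnknownReferenceError(GexmapError):
    """A query referenced a sample or gene that the dataset does not contain."""
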