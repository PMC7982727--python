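"""Exception hierarchy for pddikit.

All package errors derive from :class:`PddiError` so callers can catch one
base class; most also derive from the matching built-in (``ValueError``,
``KeyError``) so idiomatic handling keeps working.
"""


class PddiError(Exception):
    """Base class for all pddikit errors."""


class CardinalityError(PddiError, ValueError):
    """A slot has too few (or too many) entries, e.g. fewer than two drugs."""


class DanglingReferenceError(PddiError, ValueError):
    """An evidence reference does not resolve to any evidence item id."""


class VocabularyError(PddiError, ValueError):
    """A token is not part of the required controlled vocabulary."""


class FrequencyRangeError(PddiError, ValueError):
    """A frequency value is outside its admissible range (e.g. a percentage
    outside [0, 100])."""


class ValueSetConflictError(PddiError, ValueError):
    """Registering a value set under an id that is already taken."""


class MissingValueSetError(PddiError, KeyError):
    """A value-set reference does not resolve in the registry."""


class FormatError(PddiError, ValueError):
    """A value-set file is malformed (missing columns, empty, bad JSON)."""


class UnitError(PddiError, ValueError):
    """An observation's unit does not match the question's unit."""


class MissingDataError(PddiError, ValueError):
    """Strict-policy tree evaluation hit a question it cannot answer."""


class ComplexityGuardError(PddiError, ValueError):
    """Exhaustive completion enumeration would exceed the unknown-question cap."""


class DocumentParseError(PddiError, ValueError):
    """An interchange document is missing required keys or is malformed."""


class RenderError(PddiError, ValueError):
    """Narrative rendering failed (e.g. a dangling evidence reference)."""
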