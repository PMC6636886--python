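"""Exception hierarchy.

All package errors derive from :class:`BctMoaError` so callers can catch one
base class; subclasses distinguish configuration problems (bad shipped data),
schema problems (malformed input files), and corpus validation failures.
"""


class BctMoaError(Exception):
    """Base class for all package errors."""


class RegistryError(BctMoaError):
    """A shipped or user-supplied registry file is corrupt or inconsistent."""


class SchemaError(BctMoaError):
    """An input file is missing a required column or has a malformed header."""


class CorpusValidationError(BctMoaError):
    """Corpus content violates a hard constraint (unknown codes, bad rows)."""


class ReferentialIntegrityError(CorpusValidationError):
    """A link references an article or BCT coding that does not exist."""


class FixtureError(BctMoaError):
    """A packaged result fixture is missing, empty, or internally inconsistent."""


class ConfigurationError(BctMoaError):
    """A run or simulation configuration is infeasible or out of range."""


class DegenerateInputError(BctMoaError):
    """An operation received an input it is mathematically undefined for."""
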