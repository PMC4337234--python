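"""Exception types shared across the package."""


class PatternGridError(Exception):
    """Base class for all package-specific errors."""


class CodingFormatError(PatternGridError):
    """A table is missing required columns or is structurally unreadable."""


class CodingParseError(PatternGridError):
    """A cell could not be parsed as an ordinal rating."""


class IntegrityError(PatternGridError):
    """Duplicate keys with conflicting values, or other dataset corruption."""


class ContractError(PatternGridError, ValueError):
    """An argument violates a documented precondition."""


class MissingNodeError(PatternGridError):
    """A pattern profile could not be computed because a node is missing."""


class DegenerateDataError(PatternGridError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
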