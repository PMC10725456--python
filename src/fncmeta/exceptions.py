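"""Exception hierarchy shared across the pipeline stages."""


class FncMetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FncMetaError):
    """A required column or field is missing or malformed at the table level."""


class ParseError(FncMetaError):
    """A row-level parsing failure; the message names the offending record."""


class DomainError(FncMetaError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class StageRefusal(FncMetaError, RuntimeError):
    """A stage declines to run because its preconditions are not met
    (e.g. a subgroup with too few datasets). Not a crash: orchestrators
    may log it and continue."""


class DependencyError(FncMetaError):
    """A pipeline stage was requested without the outputs it depends on."""
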