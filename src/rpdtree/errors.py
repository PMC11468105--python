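"""Exception hierarchy.

Every failure mode is a distinct class so callers (and the CLI exit-code
mapping) can tell schema problems from contract violations from lookups
that left the table.
"""


class RpdTreeError(Exception):
    """Base class for all package errors."""


class SchemaError(RpdTreeError):
    """An input file does not have the expected columns."""


class ValidationError(RpdTreeError):
    """A value violates a domain invariant (e.g. q outside [0, 1])."""


class TableLookupError(RpdTreeError):
    """A (sex, age, year) query left the declared range of a life table.

    Extrapolating silently would corrupt RPD values unnoticed, so any
    out-of-range trajectory is a hard error naming the offending key.
    """


class ContractError(RpdTreeError):
    """An operation was called outside its precondition."""


class ConfigError(RpdTreeError):
    """Invalid configuration or hyperparameters."""
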