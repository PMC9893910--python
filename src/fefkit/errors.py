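"""Exception hierarchy.

Configuration problems (bad column maps, missing coefficient rows, invalid
weights) are distinguished from data-validation problems (negative loads,
duplicate keys, inconsistent ET) so the CLI can map them to distinct exit
codes (2 and 3 respectively).
"""


class FefkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FefkitError):
    """A configuration, column map, or coefficient table is wrong or incomplete."""


class DataValidationError(FefkitError):
    """Input data violates an invariant (negative load, duplicate key, ...)."""


class DomainError(DataValidationError):
    """A scalar argument is outside the mathematical domain of an operation."""


class DegenerateInputError(DataValidationError):
    """An input series is degenerate for the requested procedure (e.g. all-zero)."""
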