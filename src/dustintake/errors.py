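"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit-code convention):
``ConfigError`` for malformed configuration or scenario files, and
``DataError`` for inputs that parse but violate a statistical precondition.
"""


class DustintakeError(Exception):
    """Base class for all package errors."""


class ConfigError(DustintakeError):
    """Malformed or inconsistent configuration / scenario file."""


class DataError(DustintakeError, ValueError):
    """Input data violates a precondition of an operation."""


class InvalidSummaryError(DataError):
    """Summary moments are unusable (non-positive mean, negative SD)."""


class InvalidTableError(DataError):
    """Percentile table malformed (duplicate probabilities, decreasing values)."""


class InvalidLODError(DataError):
    """Detection limit is non-positive."""


class InsufficientDataError(DataError):
    """Too few observations / entries / replicates for the operation."""


class InvalidCompositionError(DataError):
    """Lognormal product/quotient requested with no numerator terms."""


class InvalidAggregationError(DataError):
    """Route aggregation across scenarios with mixed compounds or ADIs."""


class EmptyComparisonError(DataError):
    """Route comparison with no overlapping percentile grid."""


class UndefinedDecompositionError(DataError):
    """Variance decomposition of an all-degenerate scenario."""
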