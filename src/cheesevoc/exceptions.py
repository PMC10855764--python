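"""Exception hierarchy shared across the package.

Three broad families map onto the CLI exit codes: configuration problems
(exit 2), data problems (exit 3) and numerical failures (exit 4).
"""


class CheeseVocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CheeseVocError):
    """Invalid configuration: bad schema, missing template, bad counts."""


class DataError(CheeseVocError):
    """Invalid or inconsistent input data."""


class NumericalError(CheeseVocError):
    """A numerical procedure failed (singular fit, undefined statistic)."""


class MissingInternalStandardError(DataError):
    """No internal-standard peak found in a sample's records."""


class AmbiguousInternalStandardError(DataError):
    """More than one internal-standard peak found in a sample."""


class DegenerateInternalStandardError(DataError):
    """Internal-standard peak present but with zero area."""


class RetentionIndexRangeError(DataError):
    """Retention time outside the alkane ladder span; no extrapolation."""


class SingularFitError(NumericalError):
    """Rank-deficient model matrix in a least-squares fit."""
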