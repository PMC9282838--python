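"""Exception hierarchy shared across the pipeline.

CLI exit codes: ValidationError -> 2, DegenerateDataError -> 3.
"""


class DSClocksError(Exception):
    """Base class for all package errors."""


class ValidationError(DSClocksError):
    """Malformed input: bad headers, out-of-range values, inconsistent shapes."""


class ConfigurationError(ValidationError):
    """Inconsistent simulation or pipeline configuration."""


class DegenerateDataError(DSClocksError):
    """Structurally valid input on which the requested computation is undefined
    (rank-deficient reference, constant regressor, empty group, ...)."""
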