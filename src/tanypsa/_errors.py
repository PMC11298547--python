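class TanypsaError(Exception):
    """Base class for all package errors."""


class ConfigError(TanypsaError):
    """Invalid simulation or run configuration; the message names the offending field."""


class FormatError(TanypsaError):
    """Malformed on-disk input (MatrixMarket directory, LR database, ...)."""


class ParameterError(TanypsaError):
    """Out-of-range analysis parameter."""


class DegenerateInputError(TanypsaError):
    """Input carries no usable signal for the requested operation."""
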