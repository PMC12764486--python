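"""Exception hierarchy shared across the package."""


class EchoVidError(Exception):
    """Base class for all package errors."""


class DecodeError(EchoVidError):
    """A video file could not be parsed."""


class EmptyVideoError(EchoVidError):
    """A video decoded to zero frames."""


class ConfigurationError(EchoVidError):
    """Invalid or inconsistent configuration (e.g. non-divisible strides)."""


class ParameterError(EchoVidError):
    """An operation parameter violates its contract."""


class DataError(EchoVidError):
    """Input data violates an invariant (non-finite pixels, bad labels, ...)."""


class ContractError(EchoVidError):
    """Two in-memory artifacts disagree (mask vs sequence length, ...)."""
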