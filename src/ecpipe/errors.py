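"""Exception hierarchy for the effective-connectivity pipeline."""


class EcpipeError(Exception):
    """Base class for all pipeline errors."""


class ChannelCountError(EcpipeError):
    """A recording does not contain the channels the layout requires."""


class ParseError(EcpipeError):
    """A file could not be parsed; message carries row/column location."""


class ConfigError(EcpipeError):
    """A configuration value violates an invariant."""


class LengthError(EcpipeError):
    """A signal is too short for the requested operation."""


class ResolutionError(EcpipeError):
    """A frequency band cannot be resolved on the given record."""


class IntegrationError(EcpipeError):
    """Numerical integration of the oscillator system became unstable."""


class DegenerateInputError(EcpipeError):
    """The input has no variability to resample (e.g. a constant signal)."""


class GroupingError(EcpipeError):
    """Inputs to a group-level operation are not homogeneous."""
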