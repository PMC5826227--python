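"""Exception hierarchy shared across the simulator."""


class EvConvError(Exception):
    """Base class for all package errors."""


class ParseError(EvConvError):
    """Malformed input file (carries the offending line/record number)."""


class StreamValidationError(EvConvError):
    """An event stream violates its declared invariants."""


class ConfigurationError(EvConvError):
    """Invalid unit/network configuration."""


class RoutingError(EvConvError):
    """Event header points outside the node grid."""
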