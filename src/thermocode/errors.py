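"""Exception types shared across the package."""


class ThermocodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ThermocodeError, ValueError):
    """A parameter violates its documented precondition."""


class OutOfRangeError(ThermocodeError, ValueError):
    """A query falls outside the span of a trace or window."""


class FormatError(ThermocodeError, ValueError):
    """A file does not conform to the expected on-disk format."""
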