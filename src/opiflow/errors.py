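"""Exception types shared across the package."""


class OpiflowError(Exception):
    """Base class for all package errors."""


class StateError(OpiflowError):
    """A stock state violates an invariant (e.g. a negative stock)."""


class ScheduleRangeError(OpiflowError):
    """A time-varying input was requested outside its covered range."""


class ConfigError(OpiflowError):
    """A configuration value is missing, unknown, or out of bounds."""


class ParseError(OpiflowError):
    """An input file could not be parsed into the expected schema."""
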