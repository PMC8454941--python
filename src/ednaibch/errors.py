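"""Typed errors raised by validation, parsing and configuration."""


class EdnaIbchError(Exception):
    """Base class for all package errors."""


class FormatError(EdnaIbchError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(EdnaIbchError):
    """Parsed data violates a structural invariant."""


class ConfigError(EdnaIbchError):
    """A configuration value is out of range or inconsistent."""
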