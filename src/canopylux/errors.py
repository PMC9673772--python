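"""Exception hierarchy.

CLI exit-code mapping: :class:`ConfigError` -> 1 (usage/configuration),
:class:`DataFormatError` and :class:`DomainError` -> 2 (data problems).
"""


class CanopyLuxError(Exception):
    """Base class for all canopylux errors."""


class DomainError(CanopyLuxError, ValueError):
    """A value is outside the physical or mathematical domain of an operation."""


class ConfigError(CanopyLuxError):
    """Invalid or inconsistent configuration (unknown keys, missing roles, ...)."""


class DataFormatError(CanopyLuxError):
    """An input file does not match the expected schema."""
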