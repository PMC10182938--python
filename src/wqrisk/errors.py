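"""Exception hierarchy.

``InputError`` covers bad data handed to an operation (CLI exit code 1),
``ConfigError`` covers bad configuration files or specs (also exit code 1);
anything else escaping a command is an internal error (exit code 2).
"""


class WqriskError(Exception):
    """Base class for all package errors."""


class InputError(WqriskError):
    """Invalid data value or malformed input table."""


class ConfigError(WqriskError):
    """Invalid or missing configuration (registry, curves, YAML specs)."""


class RegistryError(ConfigError):
    """A parameter key cannot be resolved against the parameter registry."""
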