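"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2, ``ConfigError`` to exit code 3.
"""


class FusionError(Exception):
    """Base class for all focusfuse errors."""


class InputError(FusionError):
    """Bad or unreadable input data (CLI exit code 2)."""


class DimensionMismatchError(InputError):
    """Frames (or images handed to an operation) disagree in shape."""


class EmptyStackError(InputError):
    """No readable frames were found."""


class ConfigError(FusionError):
    """Invalid configuration value (CLI exit code 3)."""
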