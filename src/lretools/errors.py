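"""Exception hierarchy.

``InputError`` covers malformed user-supplied files and arguments and maps
to exit code 2 on the command line; everything else maps to exit code 1.
"""


class LreToolsError(Exception):
    """Base class for all package-specific errors."""


class InputError(LreToolsError, ValueError):
    """Malformed or inconsistent user input (bad file, bad identifier, ...)."""


class ConfigurationError(LreToolsError, ValueError):
    """Internally contradictory configuration or generator options."""


class GenerationError(LreToolsError, RuntimeError):
    """A synthetic construct cannot be realised under the active model."""
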