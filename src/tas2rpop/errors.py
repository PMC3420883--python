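"""Exception hierarchy shared across the package."""


class Tas2rPopError(Exception):
    """Base class for all package errors."""


class InputError(Tas2rPopError, ValueError):
    """Malformed or inconsistent user-supplied input."""


class AlignmentShapeError(InputError):
    """Sequences in one alignment do not share a common aligned length."""


class AlphabetError(InputError):
    """A sequence contains characters outside {A, C, G, T, N, -}."""


class ConfigError(Tas2rPopError, ValueError):
    """Invalid simulation or pipeline configuration."""
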