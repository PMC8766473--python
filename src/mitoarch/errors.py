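"""Exception hierarchy shared across the package."""


class MitoarchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MitoarchError):
    """A flat file could not be parsed; the message names the offending line."""


class ValidationError(MitoarchError):
    """Input violated a documented contract (coordinates, sizes, columns...)."""


class UnsupportedFeatureError(MitoarchError):
    """Feature form explicitly out of scope (e.g. origin-spanning locations)."""


class LengthError(MitoarchError):
    """Sequence length inconsistent with annotation coordinates."""


class InfeasibleSpecError(MitoarchError):
    """A simulation spec cannot be realized; the message names the genes."""
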