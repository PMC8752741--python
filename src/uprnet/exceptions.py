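"""Exception hierarchy shared across the package."""


class UprnetError(Exception):
    """Base class for all package errors."""


class FormatError(UprnetError):
    """Malformed input file (bad column, coordinate, or character)."""


class ConsistencyError(UprnetError):
    """Inputs that are individually valid but mutually inconsistent."""


class DesignError(UprnetError):
    """Experimental design does not support the requested computation."""


class ParameterError(UprnetError):
    """Invalid parameter value."""


class NormalizationError(UprnetError):
    """Size-factor estimation failed (no gene expressed in every sample)."""
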