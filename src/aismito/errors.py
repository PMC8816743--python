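"""Exception hierarchy shared across the package."""


class AISMitoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AISMitoError):
    """A required configuration value is missing or inconsistent."""


class ValidationError(AISMitoError, ValueError):
    """An input object violates a documented invariant."""


class NoAISDetectedError(AISMitoError):
    """The AIS marker profile carries no signal to threshold."""


class NoSomaError(AISMitoError):
    """No connected component passed the soma gates."""


class InvalidCellError(AISMitoError):
    """A cell cannot be analysed (e.g. profile shorter than the central window)."""
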