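"""Exception hierarchy shared across the package."""


class PorkfreshError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PorkfreshError):
    """A generator or run configuration is internally inconsistent."""


class CalibrationError(PorkfreshError):
    """Raw-scan reflectance calibration is impossible (e.g. W <= D)."""


class SchemaError(PorkfreshError):
    """A table on disk does not match its documented schema."""


class DomainError(PorkfreshError, ValueError):
    """An argument is outside the physically meaningful domain."""
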