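"""Exception hierarchy for pivload."""


class PivloadError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PivloadError, ValueError):
    """An argument violates a documented precondition."""


class EmptyFieldError(PivloadError, ValueError):
    """A field operation received no usable (valid/defined) nodes."""


class UndefinedPressureError(PivloadError, ValueError):
    """A sampling point could not be resolved to any defined pressure node."""


class DetectionFailureError(PivloadError, ValueError):
    """Automatic midline detection found no body in the image."""


class FormatError(PivloadError, ValueError):
    """A file does not conform to the documented on-disk dialect."""


class ConfigError(PivloadError, ValueError):
    """A run configuration is incomplete or contains unknown keys."""
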