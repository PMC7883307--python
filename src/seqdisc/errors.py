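"""Exception hierarchy shared across the package."""


class SeqdiscError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeqdiscError, ValueError):
    """A file or container does not have the expected layout (e.g. a missing column)."""


class ValidationError(SeqdiscError, ValueError):
    """Data are structurally readable but violate an invariant (shapes, monotonicity...)."""


class ConfigError(SeqdiscError, ValueError):
    """A configuration value is out of its admissible range."""


class NumericalError(SeqdiscError, ArithmeticError):
    """A numerical precondition failed (e.g. non-positive baseline fluorescence)."""
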