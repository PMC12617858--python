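"""Exception types shared across the package."""


class ObscuredGPError(Exception):
    """Base class for package-specific errors."""


class DataFormatError(ObscuredGPError, ValueError):
    """Structural problem in an input table (duplicate IDs, empty file, bad cell)."""


class DegenerateTraitError(ObscuredGPError, ValueError):
    """A trait has zero variance, so z-scoring is undefined."""


class ShapeError(ObscuredGPError, ValueError):
    """Array dimensions do not line up."""


class ParameterError(ObscuredGPError, ValueError):
    """An argument is outside its valid range."""


class ConfigurationError(ObscuredGPError, ValueError):
    """Inconsistent network configuration."""


class DivergenceError(ObscuredGPError, RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedCorrelationError(ObscuredGPError, ValueError):
    """Pearson correlation requested for a constant vector."""
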