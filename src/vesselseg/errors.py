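"""Exception types shared across the package."""


class VesselSegError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VesselSegError):
    """Input data violates a precondition (wrong channels, size, shape)."""


class InvalidConfigError(VesselSegError):
    """A configuration value is out of its admissible range."""


class InvalidShapeError(VesselSegError):
    """Array shapes are incompatible with the requested operation."""


class UndefinedMetricError(VesselSegError):
    """A metric's denominator is zero; the value is undefined, not 0."""


class DivergenceError(VesselSegError):
    """Training produced a non-finite loss."""
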