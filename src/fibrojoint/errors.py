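"""Exception types shared across the package."""


class FibrojointError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FibrojointError, ValueError):
    """A configuration field is invalid; the message names the field."""


class GeometryError(FibrojointError):
    """A geometric precondition is violated (e.g. sensor footprint leaves the scene)."""


class CalibrationError(FibrojointError):
    """Calibration failed (degenerate data, failed angle, ...)."""


class EstimationError(FibrojointError):
    """A transform or parameter estimate could not be computed."""


class SchedulingError(FibrojointError):
    """An acquisition schedule is infeasible for the requested joint mode."""
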