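"""Exception hierarchy shared across the package."""


class StemTraceError(Exception):
    """Base class for all stemtrace errors."""


class InputError(StemTraceError, ValueError):
    """Raised when an input violates a documented precondition."""


class GeometryError(InputError):
    """Raised for degenerate geometric queries (e.g. coincident vertex)."""


class CalibrationError(StemTraceError):
    """Raised when no scale marker is available for pixel-to-cm calibration."""


class ValidationError(StemTraceError):
    """Raised when a computed quantity violates an internal invariant."""


class CotyledonError(StemTraceError):
    """Raised when the cotyledon node cannot be located on the bottom edge."""


class InfeasiblePlantError(StemTraceError):
    """Raised when the synthetic generator cannot fit a plant in the canvas."""
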