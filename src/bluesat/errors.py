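"""Exception types shared across the pipeline stages."""


class BluesatError(Exception):
    """Base class for all pipeline errors."""


class CalibrationError(BluesatError):
    """Raised when a trace lacks the calibration segments needed for processing."""


class FitError(BluesatError):
    """Raised when the 5PL fit fails to converge from every deterministic start."""


class PH50Undefined(BluesatError):
    """Raised when a fitted curve does not cross 50% saturation in range.

    Typical for cold, high-PO2 curves with a high residual saturation
    (lower asymptote >= 0.5) or curves whose half-saturation pH lies
    outside the observed pH span.
    """


class StepDetectionError(BluesatError):
    """Raised when no injection step is detectable in a respirometry trace."""


class DegenerateFitError(BluesatError):
    """Raised for degenerate curve sets (identical pH50s, collapsed asymptotes)."""
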