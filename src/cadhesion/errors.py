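"""Exception hierarchy for the cadhesion pipeline."""


class CadhesionError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CadhesionError):
    """A file violates the expected on-disk format (bad column, bad cell)."""


class TopologyError(CadhesionError):
    """Trajectory frames disagree on atom count or ordering."""


class ParameterError(CadhesionError):
    """A physically or statistically invalid parameter value."""


class GeometryError(CadhesionError):
    """Degenerate geometry (too few atoms, collinear selection, overlap)."""


class CalibrationError(CadhesionError):
    """Spring-constant calibration cannot proceed (e.g. zero variance)."""


class FitError(CadhesionError):
    """A model fit failed irrecoverably after bounded restarts."""


class NormalizationError(CadhesionError):
    """FRAP normalization is impossible (pre-bleach signal <= background)."""


class PlacementError(CadhesionError):
    """Synthetic blobs cannot be placed without touching."""


class AnalysisError(CadhesionError):
    """An analysis-stage precondition is violated (window, sample count)."""
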