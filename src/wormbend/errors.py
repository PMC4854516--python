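"""Exception hierarchy.

All package errors derive from :class:`WormbendError` so callers can catch
one base class; subclasses distinguish configuration mistakes from data that
is degenerate or fails quality control.
"""


class WormbendError(Exception):
    """Base class for all wormbend errors."""


class ConfigurationError(WormbendError, ValueError):
    """A parameter or configuration value is invalid; the message names the field."""


class DataError(WormbendError, ValueError):
    """Input data is degenerate (empty, constant, zero-variance, ...)."""


class SegmentationError(DataError):
    """No foreground found when binarizing a frame."""


class EndpointError(DataError):
    """Head/tail candidates could not be located on the boundary."""


class OrientationError(DataError):
    """Head/tail orientation is ambiguous (no coherent wave propagation)."""


class CenterlineError(DataError):
    """Midline extraction failed (e.g. coiled or self-touching posture)."""


class QualityError(DataError):
    """Too many failed frames or too few frames for a reliable statistic."""


class NormalizationError(DataError):
    """Trace normalization undefined (constant trace)."""


class WaveSpeedError(DataError):
    """No coherent traveling wave in the kymograph."""


class RenderError(WormbendError, ValueError):
    """Synthetic worm could not be rendered into the requested image."""


class FitError(WormbendError, RuntimeError):
    """Model fitting failed to converge or the system is singular."""
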