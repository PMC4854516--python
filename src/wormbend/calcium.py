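"""Fluorescence extraction and normalization for single-cell calcium imaging.

Total ROI intensity is measured per frame after subtracting a background
estimate (mean of a user-drawn background region, matching the manual
workflow of soma imaging).  Traces are normalized per recording to
(F - F_min) / (F_max - F_min), which maps the dimmest frame to 0 and the
brightest to 1 and is invariant under positive affine rescaling of the raw
intensities.  A GCaMP/RFP ratio removes motion and expression artifacts
common to both channels.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence, Union

import numpy as np

from .containers import FluorescenceTrace
from .errors import ConfigurationError, DataError, NormalizationError

__all__ = ["roi_intensity", "extract_trace", "normalize_trace", "ratio_trace"]


def roi_intensity(
    frame: np.ndarray,
    roi: np.ndarray,
    background: Union[np.ndarray, float],
) -> float:
    """Background-subtracted total intensity of a region of interest.

    ``roi`` is a boolean mask; ``background`` is either a boolean mask (its
    mean pixel value is the estimate) or a precomputed scalar.  ROI and
    background must not overlap.
    """
    frame = np.asarray(frame, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != frame.shape:
        raise ConfigurationError("roi mask must match the frame shape")
    if not roi.any():
        raise DataError("empty ROI")
    if isinstance(background, np.ndarray) or (
        hasattr(background, "shape") and getattr(background, "ndim", 0) == 2
    ):
        bg_mask = np.asarray(background).astype(bool)
        if bg_mask.shape != frame.shape:
            raise ConfigurationError("background mask must match the frame shape")
        if not bg_mask.any():
            raise DataError("empty background region")
        if (roi & bg_mask).any():
            raise ConfigurationError("roi and background regions overlap")
        bg = float(frame[bg_mask].mean())
    else:
        bg = float(background)
    return float((frame[roi] - bg).sum())


def extract_trace(
    movie: Sequence[np.ndarray],
    roi: np.ndarray,
    background: Union[np.ndarray, float],
    frame_rate: float,
    *,
    label: str = "",
) -> FluorescenceTrace:
    """Apply :func:`roi_intensity` frame by frame."""
    raw = np.array([roi_intensity(f, roi, background) for f in movie])
    return FluorescenceTrace(raw=raw, frame_rate=frame_rate, label=label)


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Fill ``normalized`` with (F - F_min) / (F_max - F_min).

    Raises :class:`NormalizationError` for a constant trace (F_max = F_min).
    """
    if len(trace.raw) < 2:
        raise DataError("need at least 2 frames to normalize")
    f_min, f_max = trace.f_min, trace.f_max
    if f_max == f_min:
        raise NormalizationError("constant trace: F_max equals F_min")
    norm = (trace.raw - f_min) / (f_max - f_min)
    return replace(trace, normalized=norm)


def ratio_trace(
    gcamp: FluorescenceTrace, reference: FluorescenceTrace
) -> np.ndarray:
    """Elementwise GCaMP / reference (e.g. RFP) intensity ratio.

    Both traces must share length and frame rate and the reference must be
    strictly positive.  Multiplicative artifacts common to both channels
    (bleaching, motion, expression level) cancel in the ratio.
    """
    if len(gcamp.raw) != len(reference.raw):
        raise ConfigurationError("traces must have equal length")
    if gcamp.frame_rate != reference.frame_rate:
        raise ConfigurationError("traces must share a frame rate")
    if np.any(reference.raw <= 0):
        raise DataError("reference trace must be strictly positive")
    return gcamp.raw / reference.raw
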