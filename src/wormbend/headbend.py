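"""Head-bending measures: curvature amplitude and the ellipse-orientation index.

Two complementary readouts of head bending are used depending on the
recording geometry.  For freely moving, tracked worms the head curvature is
the mean dimensionless curvature of the anterior 18 of 100 body segments and
its amplitude is the population standard deviation of that trace over the
measurement.  For head-restrained (microfluidic) recordings, where only the
head sweeps, bending is read out as the orientation of an ellipse fitted to
the moving head ROI, normalized to a [-1, 1] index with ventral positive.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .containers import BendingTrace, CurvatureKymograph
from .errors import ConfigurationError, DataError, QualityError

__all__ = ["head_curvature", "head_bending_amplitude", "ellipse_bending_index"]


def head_curvature(
    kymograph: CurvatureKymograph, head_fraction: float = 0.18
) -> BendingTrace:
    """Per-frame mean curvature of the anterior head region.

    With the standard 100 segments and ``head_fraction`` 0.18 this averages
    columns 0-17 (the first 18 segments from the nose tip).  Missing frames
    propagate as NaN.
    """
    n_head = int(round(head_fraction * kymograph.n_segments))
    if n_head < 1 or n_head > kymograph.n_segments:
        raise ConfigurationError("head_fraction leaves no valid head segments")
    values = kymograph.values[:, :n_head].mean(axis=1)  # NaN rows stay NaN
    return BendingTrace(values=values, frame_rate=kymograph.frame_rate)


def head_bending_amplitude(trace: BendingTrace, min_frames: int = 150) -> float:
    """Population standard deviation of head curvature over the measurement.

    Requires at least ``min_frames`` valid frames (default 150, i.e. 30 s at
    5 Hz); reversal/turn frames are expected to have been excluded upstream.
    """
    vals = trace.values[np.isfinite(trace.values)]
    if len(vals) < min_frames:
        raise QualityError(
            f"only {len(vals)} valid frames; {min_frames} required for an amplitude"
        )
    return float(vals.std())  # population formula (divide by N)


def ellipse_bending_index(
    masks: Sequence[np.ndarray],
    reference_frame: Optional[int] = None,
    *,
    ventral_sign: int = 1,
    frame_rate: float = 5.0,
    min_eccentricity: float = 0.2,
) -> BendingTrace:
    """Ellipse-orientation head-deflection index in [-1, 1], ventral positive.

    Each head-ROI mask is fitted with an ellipse via second-order image
    moments; the per-frame orientation is unwrapped (period pi, to avoid
    +/-90 degree jumps) and referenced to the minimum-bending frame —
    automatically the frame whose orientation is closest to the median,
    unless ``reference_frame`` overrides it.  The deflection is then
    normalized by its maximum magnitude.  Near-circular frames (orientation
    undefined) are marked missing.
    """
    if len(masks) == 0:
        raise DataError("no frames supplied")
    angles = np.full(len(masks), np.nan)
    for i, m in enumerate(masks):
        m = np.asarray(m).astype(bool)
        if not m.any():
            continue
        props = measure.regionprops(m.astype(int))[0]
        if props.eccentricity < min_eccentricity:
            continue  # orientation undefined for a near-circular blob
        angles[i] = props.orientation  # rad, in (-pi/2, pi/2]
    valid = np.isfinite(angles)
    if valid.sum() < 2:
        raise DataError("fewer than two frames with a defined ellipse orientation")
    unwrapped = angles.copy()
    unwrapped[valid] = np.unwrap(angles[valid], period=np.pi)
    if reference_frame is None:
        med = np.nanmedian(unwrapped)
        reference_frame = int(np.nanargmin(np.abs(unwrapped - med)))
    if not np.isfinite(unwrapped[reference_frame]):
        raise ConfigurationError("reference frame has no defined orientation")
    deflection = unwrapped - unwrapped[reference_frame]
    max_def = np.nanmax(np.abs(deflection))
    if max_def == 0:
        warnings.warn("constant ellipse orientation; bending index is all zero",
                      stacklevel=2)
        index = np.where(valid, 0.0, np.nan)
    else:
        index = ventral_sign * deflection / max_def
    return BendingTrace(values=index, frame_rate=frame_rate, normalized=True)
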