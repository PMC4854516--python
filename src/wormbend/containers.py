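"""Core data containers shared across the pipeline.

Conventions
-----------
* Curvature is stored body-length normalized (dimensionless ``kappa * L``);
  positive curvature means ventral bending.
* Centerlines are ordered head (index 0) to tail, in millimetres, with the
  y axis increasing upward (image row 0 is the top of the frame).
* Missing frames are NaN rows, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "WormFrame",
    "Centerline",
    "CurvatureKymograph",
    "BendingTrace",
    "FluorescenceTrace",
    "CrossCorrelogram",
    "Bout",
]


@dataclass
class WormFrame:
    """A single binarized frame of a one-worm movie."""

    mask: np.ndarray          # 2-D boolean
    timestamp: float = 0.0    # seconds
    mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ConfigurationError("mask must be a 2-D image")
        if self.mm_per_px <= 0:
            raise ConfigurationError("mm_per_px must be positive")


@dataclass
class Centerline:
    """Arclength-resampled worm midline for one frame, head at index 0.

    ``points`` holds ``n_segments + 1`` ordered (x, y) positions in mm with
    (near-)uniform spacing along the body.
    """

    points: np.ndarray                 # (n+1, 2) in mm
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ConfigurationError("points must be an (n, 2) array with n >= 3")

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arclength(self) -> float:
        """Total body length in mm."""
        return float(self.segment_lengths.sum())

    @property
    def tangent_angles(self) -> np.ndarray:
        """Unwrapped tangent angle (rad) at each segment midpoint."""
        d = np.diff(self.points, axis=0)
        return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


@dataclass
class CurvatureKymograph:
    """Time x segment matrix of signed dimensionless curvature (kappa * L).

    Rows are frames, columns run head to tail.  Failed frames are NaN rows
    and listed in ``failed_frames``.
    """

    values: np.ndarray                       # (T, n_segments)
    frame_rate: float                        # Hz
    body_length: float = 1.0                 # mm, representative (mean) length
    body_lengths: Optional[np.ndarray] = None  # per-frame lengths, mm
    failed_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D (time x segment) array")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.body_lengths is not None:
            self.body_lengths = np.asarray(self.body_lengths, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def segment_midpoints(self) -> np.ndarray:
        """Body coordinate s in [0, 1] at segment midpoints."""
        n = self.n_segments
        return (np.arange(n) + 0.5) / n

    def plot(self, ax=None, *, cmap: str = "RdBu_r", vmax: Optional[float] = None):
        """Kymograph heat map: time down, head-to-tail across, ventral red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if vmax is None:
            finite = self.values[np.isfinite(self.values)]
            vmax = float(np.abs(finite).max()) if finite.size else 1.0
        im = ax.imshow(
            self.values, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
            extent=(0.0, 1.0, self.n_frames / self.frame_rate, 0.0),
        )
        ax.set_xlabel("body coordinate (head → tail)")
        ax.set_ylabel("time (s)")
        plt.colorbar(im, ax=ax, label=r"curvature $\kappa \cdot L$")
        return ax


@dataclass
class BendingTrace:
    """Head-bending time series: dimensionless curvature or an index in [-1, 1]."""

    values: np.ndarray
    frame_rate: float
    normalized: bool = False       # True for the ellipse-orientation index
    ventral_positive: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("values must be 1-D")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.normalized:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ConfigurationError("normalized bending index must lie in [-1, 1]")


@dataclass
class FluorescenceTrace:
    """Background-subtracted ROI fluorescence, with min-max normalization.

    ``normalized`` is ``(F - F_min) / (F_max - F_min)`` and is filled by
    :func:`wormbend.calcium.normalize_trace`.
    """

    raw: np.ndarray               # a.u. per frame
    frame_rate: float             # Hz
    normalized: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1:
            raise ConfigurationError("raw must be 1-D")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")

    @property
    def f_min(self) -> float:
        return float(np.nanmin(self.raw))

    @property
    def f_max(self) -> float:
        return float(np.nanmax(self.raw))

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.raw)) / self.frame_rate


@dataclass
class CrossCorrelogram:
    """Pearson correlation coefficient at each integer-frame lag.

    Positive lag means the response follows the input.  ``t_p`` stores the
    control-group reference peak time once assigned.
    """

    lags: np.ndarray              # seconds, symmetric about 0
    coefficients: np.ndarray      # in [-1, 1], NaN where overlap too short
    input_label: str = "bending"
    response_label: str = "calcium"
    t_p: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.lags.shape != self.coefficients.shape:
            raise ConfigurationError("lags and coefficients must have equal shape")
        finite = self.coefficients[np.isfinite(self.coefficients)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ConfigurationError("correlation coefficients must lie in [-1, 1]")


@dataclass
class Bout:
    """One contiguous episode of forward locomotion and its kinematics.

    Frame range is half-open ``[start, stop)``.  Kinematic fields are filled
    by :mod:`wormbend.rft`.
    """

    start: int
    stop: int
    frame_rate: float
    v_a: Optional[float] = None          # mm/s, actual centroid speed
    v_w: Optional[float] = None          # mm/s, undulation wave speed (worm frame)
    theta_a: Optional[float] = None      # degrees, angle of attack
    efficiency: Optional[float] = None   # V_a / V_w
    head_amplitude: Optional[float] = None  # dimensionless curvature SD

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ConfigurationError("bout stop must exceed start")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def duration(self) -> float:
        """Bout duration in seconds (span between first and last frame)."""
        return (self.stop - 1 - self.start) / self.frame_rate

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.stop)
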