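"""Synthetic worm movies, calcium traces and locomotion bouts with ground truth.

The generator emulates the study conditions the analysis targets: a
dorsoventrally undulating worm whose curvature wave travels head to tail at
about 1 Hz, imaged as a binary silhouette at 5 Hz; GCaMP-like traces
phase-locked to local dorsal/ventral head bending; and bout-level
(angle-of-attack, efficiency) pairs drawn from the small-angle
resistive-force-theory relation with observation noise.

Every randomized generator is a pure function of its ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import label as _cc_label

from .containers import Centerline, CurvatureKymograph, FluorescenceTrace, WormFrame
from .errors import ConfigurationError, RenderError

__all__ = [
    "WaveParams",
    "GroundTruth",
    "make_curvature_wave",
    "centerline_from_curvature",
    "default_width_profile",
    "render_worm_mask",
    "make_synthetic_movie",
    "make_calcium_traces",
    "make_rft_bouts",
]


@dataclass
class WaveParams:
    """Parameters of the traveling dorsoventral curvature wave.

    ``curvature_amplitude`` is dimensionless (kappa * L).  The default 3.0
    gives a tangent-angle amplitude of about 27 degrees for a one-wavelength
    body, a typical crawling posture.  ``wavelength_fraction`` is the spatial
    period as a fraction of body length; ``frequency`` defaults to the ~1 Hz
    undulation of forward locomotion, sampled at an effective 5 Hz.
    """

    curvature_amplitude: float = 3.0   # kappa * L, dimensionless
    wavelength_fraction: float = 1.0   # body lengths per spatial period
    frequency: float = 1.0             # Hz
    duration: float = 30.0             # s
    frame_rate: float = 5.0            # Hz
    n_segments: int = 100
    body_length: float = 1.0           # mm
    noise_sd: float = 0.0              # dimensionless curvature
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ConfigurationError("frequency must be > 0")
        if not (0 < self.wavelength_fraction <= 2):
            raise ConfigurationError("wavelength_fraction must be in (0, 2]")
        if not self.frame_rate > 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.n_segments < 10:
            raise ConfigurationError("n_segments must be >= 10")
        if not self.duration > 0:
            raise ConfigurationError("duration must be > 0")
        if not self.body_length > 0:
            raise ConfigurationError("body_length must be > 0")
        if self.curvature_amplitude < 0:
            raise ConfigurationError("curvature_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic dataset; same time base as the movie."""

    kymograph: CurvatureKymograph
    centerlines: Sequence[Centerline] = field(default_factory=list)
    head_index: int = 0
    calcium_lag: Optional[float] = None   # s
    drag_ratio: Optional[float] = None    # C_perp / C_par, when bouts generated
    params: Optional[WaveParams] = None
    track: Optional[np.ndarray] = None    # (T, 2) centroid positions, mm


def make_curvature_wave(params: WaveParams) -> CurvatureKymograph:
    """Posteriorly traveling sine wave of body curvature.

    kappa*L(s, t) = A sin(2 pi f t - 2 pi s / lambda) + eps,
    evaluated at segment midpoints s in [0, 1]; eps ~ N(0, noise_sd^2).
    Phase velocity is positive head (s=0) to tail (s=1).
    """
    t = np.arange(params.n_frames) / params.frame_rate
    s = (np.arange(params.n_segments) + 0.5) / params.n_segments
    phase = 2 * np.pi * (params.frequency * t[:, None] - s[None, :] / params.wavelength_fraction)
    values = params.curvature_amplitude * np.sin(phase)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
    return CurvatureKymograph(
        values=values,
        frame_rate=params.frame_rate,
        body_length=params.body_length,
        body_lengths=np.full(params.n_frames, params.body_length),
    )


def centerline_from_curvature(
    curvature_row: np.ndarray,
    body_length: float = 1.0,
    *,
    frame_index: int = 0,
    origin: Union[np.ndarray, tuple] = (0.0, 0.0),
    heading: float = 0.0,
) -> Centerline:
    """Integrate a curvature profile into an inextensible midline.

    The tangent angle is the running integral of curvature; positions are the
    running integral of the tangent.  The mean tangent angle is set by
    ``heading`` (radians) and the centroid by ``origin``, so the returned
    midline has total arclength ``body_length`` exactly (by construction each
    of the ``n`` steps has length ``body_length / n``).
    """
    k = np.asarray(curvature_row, dtype=float)
    if k.ndim != 1 or len(k) < 2:
        raise ConfigurationError("curvature_row must be a 1-D vector with >= 2 segments")
    if not np.all(np.isfinite(k)):
        raise ConfigurationError("curvature_row must be finite")
    if body_length <= 0:
        raise ConfigurationError("body_length must be > 0")
    n = len(k)
    ds = 1.0 / n
    psi_nodes = np.concatenate([[0.0], np.cumsum(k * ds)])
    psi_mid = 0.5 * (psi_nodes[:-1] + psi_nodes[1:])
    psi_mid = psi_mid - psi_mid.mean() + heading
    step = ds * body_length
    x = np.concatenate([[0.0], np.cumsum(np.cos(psi_mid) * step)])
    y = np.concatenate([[0.0], np.cumsum(np.sin(psi_mid) * step)])
    pts = np.stack([x, y], axis=1)
    pts = pts - pts.mean(axis=0) + np.asarray(origin, dtype=float)
    return Centerline(points=pts, frame_index=frame_index)


def default_width_profile(
    body_length: float = 1.0,
    relative_width: float = 0.04,
    tip_width: float = 0.0035,
) -> Callable[[np.ndarray], np.ndarray]:
    """Sine-tapered half-width profile with blunt tips.

    w(s) = L * (tip_width + (relative_width - tip_width) * sin(pi s)):
    maximal half-width ``relative_width * L`` mid-body (0.04 L, about the
    proportions of an adult worm) tapering to a small finite tip half-width
    (3.5 um on a 1 mm body).  Real worm tips are blunt, not needle-pointed,
    and a strictly positive width keeps the whole body above the pixel scale
    of a typical recording; the tips remain the two sharpest convex features
    of the silhouette.
    """
    def profile(s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, 1.0)
        return body_length * (
            tip_width + (relative_width - tip_width) * np.sin(np.pi * s)
        )

    return profile


def render_worm_mask(
    centerline: Centerline,
    width_profile: Union[Callable, np.ndarray, None] = None,
    image_shape: tuple = (256, 256),
    mm_per_px: float = 0.005,
    *,
    timestamp: float = 0.0,
    margin_px: int = 5,
) -> WormFrame:
    """Rasterize a worm silhouette as the union of discs along the midline.

    A pixel is foreground when its distance to the (densely resampled)
    midline is at most the local half-width.  The worm must fit inside the
    image with ``margin_px`` clearance.  Image rows map to decreasing y:
    the midline's mm coordinates are placed with the image center at the
    coordinate origin.
    """
    pts = centerline.points
    L = centerline.arclength
    if width_profile is None:
        width_profile = default_width_profile(L)
    u = np.concatenate([[0.0], np.cumsum(centerline.segment_lengths)]) / L
    if callable(width_profile):
        w_nodes = np.asarray(width_profile(u), dtype=float)
    else:
        w_nodes = np.asarray(width_profile, dtype=float)
        if len(w_nodes) != len(pts):
            raise ConfigurationError("width_profile array must match centerline points")
    if np.any(w_nodes < 0) or not np.any(w_nodes > 0):
        raise RenderError("width profile must be non-negative and not identically zero")

    # dense resample so adjacent discs overlap even at sub-pixel widths
    n_dense = max(4 * len(pts), int(np.ceil(L / (0.25 * mm_per_px))))
    ud = np.linspace(0.0, 1.0, n_dense)
    xd = np.interp(ud, u, pts[:, 0])
    yd = np.interp(ud, u, pts[:, 1])
    wd = np.interp(ud, u, w_nodes)
    # discs below half a pixel cannot overlap their neighbours' pixels and
    # would rasterize as isolated specks; the silhouette ends where the body
    # is at least one pixel wide
    visible = wd >= 0.5 * mm_per_px
    if not visible.any():
        raise RenderError("rendered mask is empty (width below pixel scale everywhere)")
    xd, yd, wd = xd[visible], yd[visible], wd[visible]

    nrows, ncols = image_shape
    # mm -> px: origin at the central pixel (integer coordinates, so that an
    # axis-aligned body does not sit systematically half a pixel off-grid), y up
    col = xd / mm_per_px + ncols // 2
    row = nrows // 2 - yd / mm_per_px
    wpx = wd / mm_per_px
    if (
        np.any(col - wpx < margin_px)
        or np.any(col + wpx > ncols - 1 - margin_px)
        or np.any(row - wpx < margin_px)
        or np.any(row + wpx > nrows - 1 - margin_px)
    ):
        raise RenderError("worm does not fit inside the image with the required margin")

    r0 = max(0, int(np.floor(row.min() - wpx.max() - 1)))
    r1 = min(nrows, int(np.ceil(row.max() + wpx.max() + 2)))
    c0 = max(0, int(np.floor(col.min() - wpx.max() - 1)))
    c1 = min(ncols, int(np.ceil(col.max() + wpx.max() + 2)))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    tree = cKDTree(np.stack([row, col], axis=1))
    dist, idx = tree.query(np.stack([rr.ravel(), cc.ravel()], axis=1))
    inside = dist <= wpx[idx]
    mask = np.zeros(image_shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)

    if not mask.any():
        raise RenderError("rendered mask is empty (width below pixel scale everywhere)")
    if _cc_label(mask).max() != 1:
        raise RenderError("rendered mask is not a single connected component")
    return WormFrame(mask=mask, timestamp=timestamp, mm_per_px=mm_per_px)


def make_synthetic_movie(
    params: WaveParams,
    *,
    image_shape: tuple = (256, 256),
    mm_per_px: float = 0.005,
    width_profile: Union[Callable, np.ndarray, None] = None,
    drift_speed: float = 0.0,          # mm/s rigid translation (kinematic)
    drift_direction: tuple = (1.0, 0.0),
) -> tuple:
    """Compose wave -> centerline -> mask frame by frame.

    Returns ``(frames, ground_truth)`` where ``frames`` is a list of
    :class:`WormFrame` and the ground truth carries the kymograph, the exact
    centerlines and the centroid track on the same time base.
    """
    kymo = make_curvature_wave(params)
    d = np.asarray(drift_direction, dtype=float)
    if drift_speed != 0:
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ConfigurationError("drift_direction must be non-zero when drifting")
        d = d / norm
    frames = []
    centerlines = []
    track = np.zeros((params.n_frames, 2))
    for i in range(params.n_frames):
        t = i / params.frame_rate
        origin = drift_speed * t * d
        cl = centerline_from_curvature(
            kymo.values[i], params.body_length, frame_index=i, origin=origin
        )
        frames.append(
            render_worm_mask(
                cl, width_profile, image_shape, mm_per_px, timestamp=t
            )
        )
        centerlines.append(cl)
        track[i] = cl.points.mean(axis=0)
    gt = GroundTruth(
        kymograph=kymo,
        centerlines=centerlines,
        head_index=0,
        params=params,
        track=track,
    )
    return frames, gt


def make_calcium_traces(
    kymograph: CurvatureKymograph,
    lag: float = 0.0,
    gain: float = 1.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    head_fraction: float = 0.18,
) -> tuple:
    """GCaMP-like ventral and dorsal traces phase-locked to head bending.

    The coupling half-wave rectifies head curvature (ventral bending
    positive): the ventral-like trace rises during ventral bending, the
    dorsal-like trace during dorsal bending, so the pair is anti-correlated.
    ``lag`` delays the fluorescence response behind the bending (seconds,
    rounded to whole frames; edge frames hold the first value).
    """
    if lag < 0:
        raise ConfigurationError("lag must be >= 0")
    n_head = int(round(head_fraction * kymograph.n_segments))
    head = np.nanmean(kymograph.values[:, :n_head], axis=1)
    n = len(head)
    shift = int(round(lag * kymograph.frame_rate))
    if shift >= n:
        raise ConfigurationError("lag exceeds trace duration")
    if shift > 0:
        head = np.concatenate([np.full(shift, head[0]), head[:-shift]])
    rng = np.random.default_rng(seed)
    ventral = baseline + gain * np.maximum(head, 0.0)
    dorsal = baseline + gain * np.maximum(-head, 0.0)
    if noise_sd > 0:
        ventral = ventral + rng.normal(0.0, noise_sd, n)
        dorsal = dorsal + rng.normal(0.0, noise_sd, n)
    fr = kymograph.frame_rate
    return (
        FluorescenceTrace(raw=ventral, frame_rate=fr, label="ventral"),
        FluorescenceTrace(raw=dorsal, frame_rate=fr, label="dorsal"),
    )


def make_rft_bouts(
    K_true: float,
    n_bouts: int = 100,
    theta_range: tuple = (5.0, 45.0),
    efficiency_noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Bout-level (theta_a, efficiency) pairs on the small-angle RFT curve.

    theta_a is uniform over ``theta_range`` (degrees); efficiency is the
    closed-form small-angle value plus Gaussian noise truncated at 0
    (efficiency is a speed ratio of forward bouts).
    """
    from .rft import rft_efficiency_smallangle

    if K_true <= 1:
        raise ConfigurationError("K_true must exceed 1: no propulsion under isotropic drag")
    if n_bouts < 3:
        raise ConfigurationError("n_bouts must be >= 3")
    lo, hi = theta_range
    if not (0 <= lo < hi < 90):
        raise ConfigurationError("theta_range must satisfy 0 <= lo < hi < 90 degrees")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(lo, hi, n_bouts)
    eff = rft_efficiency_smallangle(theta, K_true)
    if efficiency_noise_sd > 0:
        eff = eff + rng.normal(0.0, efficiency_noise_sd, n_bouts)
    eff = np.maximum(eff, 0.0)
    return pd.DataFrame({"theta_a_deg": theta, "efficiency": eff})
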