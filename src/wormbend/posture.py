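"""Single-worm movie -> centerlines -> curvature kymograph.

The pipeline mirrors a standard single-worm tracker: binarize each frame,
find head and tail as the two maxima of convex boundary curvature, split the
boundary into two flanks and take their arclength-matched midline, resample
to 100 segments and differentiate the smoothed tangent angle to get signed,
body-length-normalized curvature.  Head/tail orientation is automated from
the direction of curvature-wave propagation (the head end leads the wave).

Coordinates: image (row, col) maps to mm with x = col * mm_per_px and
y increasing upward; positive curvature is ventral bending once the
dorsoventral side is known (``ventral_sign``).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes, uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .containers import Centerline, CurvatureKymograph, WormFrame
from .errors import (
    CenterlineError,
    ConfigurationError,
    EndpointError,
    OrientationError,
    QualityError,
    SegmentationError,
)

__all__ = [
    "binarize_frame",
    "find_endpoints",
    "assign_head_tail",
    "extract_centerline",
    "compute_curvature",
    "build_kymograph",
    "DEFAULT_SMOOTHING_CUTOFF",
]

# Tangent-angle smoothing cutoff in cycles per body length.  Worm undulation
# carries at most ~2.5 spatial cycles along the body (wavelength >= 0.4 L);
# 4 cycles/body passes that band essentially unattenuated (zero-phase
# 4th-order Butterworth: |H| > 0.998 at 2 cycles/body) while suppressing
# pixel-scale boundary noise.
DEFAULT_SMOOTHING_CUTOFF = 4.0


def _px_to_mm(rc: np.ndarray, shape: tuple, mm_per_px: float) -> np.ndarray:
    """(row, col) pixel coordinates -> (x, y) mm with y up."""
    rc = np.asarray(rc, dtype=float)
    x = rc[..., 1] * mm_per_px
    y = (shape[0] - 1 - rc[..., 0]) * mm_per_px
    return np.stack([x, y], axis=-1)


def binarize_frame(
    image: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    *,
    timestamp: float = 0.0,
    mm_per_px: float = 1.0,
) -> WormFrame:
    """Threshold a grayscale frame, keep the largest component, fill holes."""
    img = np.asarray(image)
    if img.size == 0:
        raise SegmentationError("empty image")
    if method == "fixed":
        if threshold is None:
            raise ConfigurationError("method='fixed' requires a threshold")
        thr = threshold
    elif method == "otsu":
        if img.min() == img.max():
            raise SegmentationError("image is uniform; no foreground")
        thr = threshold_otsu(img)
    else:
        raise ConfigurationError(f"unknown binarization method {method!r}")
    fg = img > thr
    if not fg.any():
        raise SegmentationError("no foreground pixels above threshold")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = binary_fill_holes(labels == largest)
    return WormFrame(mask=mask, timestamp=timestamp, mm_per_px=mm_per_px)


def _resampled_boundary(frame: WormFrame, n_points: int = 400,
                        smooth_frac: float = 0.02) -> np.ndarray:
    """Closed boundary of the mask, uniformly resampled by arclength and
    lightly smoothed (circular window = ``smooth_frac`` of perimeter).
    Returned as (n, 2) mm coordinates, counter-clockwise."""
    contours = measure.find_contours(frame.mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no boundary")
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    pts = _px_to_mm(contour, frame.mask.shape, frame.mm_per_px)
    # enforce counter-clockwise orientation (positive shoelace area)
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    perim = arc[-1]
    u = np.linspace(0.0, perim, n_points, endpoint=False)
    closed = np.vstack([pts, pts[:1]])
    bx = np.interp(u, arc, closed[:, 0])
    by = np.interp(u, arc, closed[:, 1])
    out = np.stack([bx, by], axis=1)
    win = max(3, int(round(smooth_frac * n_points)))
    out = uniform_filter1d(out, size=win, axis=0, mode="wrap")
    return out


def find_endpoints(
    frame: WormFrame,
    *,
    n_boundary: int = 400,
    smooth_frac: float = 0.02,
    min_separation_frac: float = 0.25,
    window_frac: float = 0.04,
    min_turning: float = 1.2,
) -> tuple:
    """Head/tail candidates: the two sharpest convex features of the boundary.

    Convexity is scored by the windowed turning angle — the integral of
    convex boundary curvature over a window of ``window_frac`` of the
    perimeter.  A worm cap turns by ~pi radians within that window, while a
    smooth bend of the body accumulates only a fraction of a radian, so the
    two body tips always outrank the outer apex of even a U-shaped posture,
    and single-pixel curvature spikes cannot masquerade as tips.  Peaks must
    exceed ``min_turning`` radians and lie at least ``min_separation_frac``
    of the perimeter apart; near-circular blobs have no qualifying peak and
    raise :class:`EndpointError`.
    """
    b = _resampled_boundary(frame, n_boundary, smooth_frac)
    n = len(b)
    d = np.roll(b, -1, axis=0) - b
    psi = np.arctan2(d[:, 1], d[:, 0])
    dpsi = np.angle(np.exp(1j * (np.roll(psi, -1) - psi)))  # wrapped turn per step
    win = max(3, int(round(window_frac * n)))
    kernel = np.ones(win)
    turning = np.real(np.fft.ifft(np.fft.fft(dpsi) * np.fft.fft(kernel, n)))
    turning = np.roll(turning, -(win // 2))  # center the window
    pad = n // 2
    wrapped = np.concatenate([turning[-pad:], turning, turning[:pad]])
    peaks, _ = find_peaks(wrapped, height=min_turning)
    peaks = np.unique(peaks[(peaks >= pad) & (peaks < pad + n)] - pad)
    if len(peaks) < 2:
        raise EndpointError(
            "fewer than two sharp convex features on the boundary "
            "(near-circular blob?)"
        )
    peaks = peaks[np.argsort(turning[peaks])[::-1]][:6]
    min_sep = min_separation_frac * n
    best = None
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            sep = abs(peaks[i] - peaks[j])
            sep = min(sep, n - sep)
            if sep < min_sep:
                continue
            score = (turning[peaks[i]] + turning[peaks[j]], sep)
            if best is None or score > best[0]:
                best = (score, (peaks[i], peaks[j]))
    if best is None:
        raise EndpointError("no convex peak pair with sufficient perimeter separation")

    def refine_tip(i0: int) -> np.ndarray:
        # the turning-angle peak localizes a blunt cap only to ~the window
        # width; take the cap point most distal from the shoulder region
        shoulder = np.arange(i0 - 2 * win, i0 + 2 * win + 1) % n
        ref = b[shoulder].mean(axis=0)
        cap = np.arange(i0 - (win + 1) // 2, i0 + (win + 1) // 2 + 1) % n
        return b[cap[np.argmax(np.linalg.norm(b[cap] - ref, axis=1))]].copy()

    i1, i2 = best[1]
    return refine_tip(i1), refine_tip(i2)


def _sample_path_at(path: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Sample an open path at the given arclength fractions."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    u = fracs * arc[-1]
    return np.stack(
        [np.interp(u, arc, path[:, 0]), np.interp(u, arc, path[:, 1])], axis=1
    )


def _matched_flank_midline(fa: np.ndarray, fb: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Midline of two flanks with curvature-corrected correspondence.

    Plain arclength-fraction matching mispairs flank points wherever the
    body bends, because the inner and outer boundary run at local rates
    (1 -/+ w * kappa) relative to the midline.  Starting from the fraction
    matching, the flank parameterizations are reweighted by those rates and
    the midline re-averaged; two iterations suffice.
    """
    M = len(fa)
    A = _sample_path_at(fa, np.linspace(0.0, 1.0, M))
    B = _sample_path_at(fb, np.linspace(0.0, 1.0, M))
    for _ in range(n_iter):
        mid = 0.5 * (A + B)
        d = np.gradient(mid, axis=0)
        ds = np.linalg.norm(d, axis=1)
        ds = np.maximum(ds, 1e-12)
        t = d / ds[:, None]
        n = np.stack([-t[:, 1], t[:, 0]], axis=1)
        psi = np.unwrap(np.arctan2(t[:, 1], t[:, 0]))
        kappa = np.gradient(psi) / ds
        w = 0.5 * np.linalg.norm(A - B, axis=1)
        side_a = np.sign(np.mean(np.sum((A - mid) * n, axis=1))) or 1.0
        rate_a = np.clip(1.0 - side_a * w * kappa, 0.2, 2.0)
        rate_b = np.clip(1.0 + side_a * w * kappa, 0.2, 2.0)
        ca = np.concatenate([[0.0], np.cumsum(0.5 * (rate_a[1:] + rate_a[:-1]) * ds[1:])])
        cb = np.concatenate([[0.0], np.cumsum(0.5 * (rate_b[1:] + rate_b[:-1]) * ds[1:])])
        A = _sample_path_at(fa, ca / ca[-1])
        B = _sample_path_at(fb, cb / cb[-1])
    return 0.5 * (A + B)


def extract_centerline(
    frame: WormFrame,
    head: np.ndarray,
    tail: np.ndarray,
    *,
    n_points: int = 101,
    n_boundary: int = 800,
    flank_points: int = 400,
    inside_tolerance: float = 0.05,
) -> Centerline:
    """Midline from head to tail, resampled to ``n_points`` equal arclengths.

    The boundary is split at head and tail into two flanks and the midline
    is the mean of correspondence-matched flank points (see
    :func:`_matched_flank_midline`).  When that midline leaves the mask
    (self-touching or coiled posture) a skeleton-path fallback is tried
    before giving up with :class:`CenterlineError`.
    """
    b = _resampled_boundary(frame, n_boundary)
    i_h = int(np.argmin(np.linalg.norm(b - np.asarray(head), axis=1)))
    i_t = int(np.argmin(np.linalg.norm(b - np.asarray(tail), axis=1)))
    if i_h == i_t:
        raise CenterlineError("head and tail map to the same boundary point")
    fa = _resample_path(_walk(b, i_h, i_t, +1), flank_points)
    fb = _resample_path(_walk(b, i_h, i_t, -1), flank_points)
    mid = _matched_flank_midline(fa, fb)
    mid = _resample_path(mid, n_points)
    if _outside_fraction(mid, frame) > inside_tolerance:
        mid = _skeleton_centerline(frame, head, tail, n_points)
        if mid is None or _outside_fraction(mid, frame) > inside_tolerance:
            raise CenterlineError("midline leaves the mask (coiled or self-touching posture)")
    return Centerline(points=mid)


def _walk(b: np.ndarray, i0: int, i1: int, step: int) -> np.ndarray:
    n = len(b)
    idx = [i0]
    i = i0
    while i != i1:
        i = (i + step) % n
        idx.append(i)
    return b[idx]


def _resample_path(path: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        raise CenterlineError("degenerate (zero-length) path")
    u = np.linspace(0.0, arc[-1], n)
    return np.stack([np.interp(u, arc, path[:, 0]), np.interp(u, arc, path[:, 1])], axis=1)


def _outside_fraction(points_mm: np.ndarray, frame: WormFrame) -> float:
    shape = frame.mask.shape
    col = np.round(points_mm[:, 0] / frame.mm_per_px).astype(int)
    row = np.round(shape[0] - 1 - points_mm[:, 1] / frame.mm_per_px).astype(int)
    ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    inside = np.zeros(len(points_mm), dtype=bool)
    inside[ok] = frame.mask[row[ok], col[ok]]
    return 1.0 - inside.mean()


def _skeleton_centerline(frame: WormFrame, head, tail, n_points: int):
    """Fallback: longest geodesic through the morphological skeleton."""
    import networkx as nx

    skel = morphology.skeletonize(frame.mask)
    rr, cc = np.nonzero(skel)
    if len(rr) < 2:
        return None
    nodes = list(zip(rr.tolist(), cc.tolist()))
    node_set = set(nodes)
    g = nx.Graph()
    for r, c in nodes:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                if (r + dr, c + dc) in node_set:
                    g.add_edge((r, c), (r + dr, c + dc),
                               weight=float(np.hypot(dr, dc)))
    pts_mm = _px_to_mm(np.array(nodes, dtype=float), frame.mask.shape, frame.mm_per_px)
    i_h = int(np.argmin(np.linalg.norm(pts_mm - np.asarray(head), axis=1)))
    i_t = int(np.argmin(np.linalg.norm(pts_mm - np.asarray(tail), axis=1)))
    try:
        path = nx.shortest_path(g, nodes[i_h], nodes[i_t], weight="weight")
    except Exception:
        return None
    path_mm = _px_to_mm(np.array(path, dtype=float), frame.mask.shape, frame.mm_per_px)
    # extend skeleton ends out to the detected tips
    path_mm = np.vstack([np.asarray(head)[None], path_mm, np.asarray(tail)[None]])
    return _resample_path(path_mm, n_points)


def _ar_extend(x: np.ndarray, npad: int, order: int = 8) -> np.ndarray:
    """Least-squares autoregressive forward extrapolation of a 1-D series."""
    n = len(x)
    if n <= 2 * order:
        return np.full(npad, x[-1])
    X = np.column_stack([x[order - 1 - i:n - 1 - i] for i in range(order)])
    coef, *_ = np.linalg.lstsq(X, x[order:], rcond=None)
    buf = list(x[-order:][::-1])  # most recent first
    out = np.empty(npad)
    for i in range(npad):
        nxt = float(np.dot(coef, buf[:order]))
        out[i] = nxt
        buf.insert(0, nxt)
    return out


def _filter_tangent(psi: np.ndarray, cutoff: float, pads: tuple) -> np.ndarray:
    """Zero-phase low-pass of the tangent angle with explicit end padding."""
    left, right = pads
    npad = len(left)
    ext = np.concatenate([left, psi, right])
    n = len(psi)
    bf, af = butter(4, min(cutoff / (n / 2), 0.99))
    # odd reflection beyond the explicit pads continues the local slope, so
    # a linear psi (constant curvature) passes through unchanged
    ext_f = filtfilt(bf, af, ext, padtype="odd", padlen=len(ext) - 1)
    return ext_f[npad:npad + n]


def compute_curvature(
    centerline: Centerline,
    *,
    smoothing_cutoff: Optional[float] = DEFAULT_SMOOTHING_CUTOFF,
    ventral_sign: int = 1,
    n_out: Optional[int] = None,
) -> np.ndarray:
    """Signed dimensionless curvature (kappa * L) at each body segment.

    The unwrapped tangent angle psi(s) is low-pass filtered along the body
    (zero-phase 4th-order Butterworth at ``smoothing_cutoff`` cycles per
    body length) and differentiated against body fraction, which directly
    yields kappa * L.  Because a low-pass filter is only as good as its
    boundary treatment, the trace is extended beyond both ends before
    filtering: a first pass uses quadratic extrapolation, and a second pass
    re-pads with an autoregressive continuation fitted to the first pass's
    smooth interior, which follows an undulatory tangent angle beyond the
    tips instead of bending it flat.  ``smoothing_cutoff=None`` skips the
    filter (plain second-order finite differences).  ``ventral_sign`` (+1 or
    -1) states which image side is ventral so that positive curvature means
    ventral bending.
    """
    L = centerline.arclength
    if L <= 0:
        raise CenterlineError("degenerate (zero-length) centerline")
    psi = centerline.tangent_angles
    n = len(psi)
    s_mid = (np.arange(n) + 0.5) / n
    ds = 1.0 / n
    if smoothing_cutoff is not None and n >= 16:
        nfit = min(24, max(4, n // 4))
        npad = min(30, n - 1)
        s_l = s_mid[0] - ds * np.arange(npad, 0, -1)
        s_r = s_mid[-1] + ds * np.arange(1, npad + 1)
        coef_l = np.polyfit(s_mid[:nfit], psi[:nfit], 2)
        coef_r = np.polyfit(s_mid[-nfit:], psi[-nfit:], 2)
        psi_f = _filter_tangent(
            psi, smoothing_cutoff,
            (np.polyval(coef_l, s_l), np.polyval(coef_r, s_r)),
        )
        # second pass: AR pads fitted on the smooth first pass (trimmed of
        # its own slightly biased ends), around a linear trend
        trend = np.polyfit(s_mid, psi_f, 1)
        resid = psi_f - np.polyval(trend, s_mid)
        trim = min(6, n // 8)
        right = _ar_extend(resid[:n - trim], npad + trim)[trim:]
        left = _ar_extend(resid[trim:][::-1], npad + trim)[trim:][::-1]
        pads = (left + np.polyval(trend, s_l), right + np.polyval(trend, s_r))
        if all(np.isfinite(p).all() for p in pads) and max(
            np.ptp(pads[0]), np.ptp(pads[1])
        ) < 10 * max(np.ptp(psi), 1e-9):
            psi_f = _filter_tangent(psi, smoothing_cutoff, pads)
    else:
        psi_f = psi
    k = np.gradient(psi_f, s_mid, edge_order=2)
    if n_out is not None and n_out != n:
        s_out = (np.arange(n_out) + 0.5) / n_out
        k = np.interp(s_out, s_mid, k)
    return ventral_sign * k


def assign_head_tail(kymograph: CurvatureKymograph, *, override: Optional[str] = None):
    """Decide which end of a provisional kymograph is the head.

    The head is the end from which the curvature wave propagates (its phase
    leads).  Returns ``True`` when index 0 already is the head, ``False``
    when the kymograph must be flipped.  ``override`` ('first' or 'last')
    bypasses the automatic decision.  Raises :class:`OrientationError` when
    no coherent propagation direction exists (e.g. a static worm).
    """
    if override == "first":
        return True
    if override == "last":
        return False
    if override is not None:
        raise ConfigurationError("override must be 'first', 'last' or None")
    if kymograph.n_frames < 5:
        raise OrientationError("need at least 5 frames to orient head/tail")
    from .rft import _phase_slope  # shared wave machinery

    try:
        _, slope, _ = _phase_slope(kymograph.values, kymograph.frame_rate)
    except Exception as exc:
        raise OrientationError(
            "no coherent wave propagation; manual head assignment required"
        ) from exc
    # phase decreasing from index 0 toward the tail end = wave leaves index 0
    return slope < 0


def _flip_kymograph_values(values: np.ndarray) -> np.ndarray:
    """Reverse head/tail traversal: column order reverses and sign flips."""
    return -values[:, ::-1]


def build_kymograph(
    frames: Sequence[WormFrame],
    *,
    head_end: str = "auto",
    n_segments: int = 100,
    smoothing_cutoff: Optional[float] = DEFAULT_SMOOTHING_CUTOFF,
    ventral_sign: int = 1,
    max_failed_fraction: float = 0.2,
) -> tuple:
    """Stack per-frame curvature rows into a kymograph.

    Endpoint order is made consistent across frames by nearest-neighbour
    matching to the previous frame; the global head/tail orientation is then
    set by wave propagation (``head_end='auto'``) or forced with ``'first'``
    / ``'last'``.  Failed frames become NaN rows (flagged, never zeros); more
    than ``max_failed_fraction`` failures raises :class:`QualityError`.

    Returns ``(kymograph, centerlines)`` with ``None`` placeholders for
    failed frames.
    """
    if len(frames) < 2:
        raise ConfigurationError("need at least 2 frames")
    timestamps = np.array([f.timestamp for f in frames], dtype=float)
    dts = np.diff(timestamps)
    frame_rate = 1.0 / np.median(dts) if np.all(dts > 0) else 1.0

    rows = np.full((len(frames), n_segments), np.nan)
    lengths = np.full(len(frames), np.nan)
    centerlines: list = []
    failed = []
    prev_ends = None
    for i, frame in enumerate(frames):
        try:
            e1, e2 = find_endpoints(frame)
            if prev_ends is not None:
                straight = np.linalg.norm(e1 - prev_ends[0]) + np.linalg.norm(e2 - prev_ends[1])
                crossed = np.linalg.norm(e1 - prev_ends[1]) + np.linalg.norm(e2 - prev_ends[0])
                if crossed < straight:
                    e1, e2 = e2, e1
            cl = extract_centerline(frame, e1, e2, n_points=n_segments + 1)
            cl.frame_index = i
            rows[i] = compute_curvature(cl, smoothing_cutoff=smoothing_cutoff,
                                        ventral_sign=ventral_sign)
            lengths[i] = cl.arclength
            centerlines.append(cl)
            prev_ends = (e1, e2)
        except Exception:
            failed.append(i)
            centerlines.append(None)
    if len(failed) > max_failed_fraction * len(frames):
        raise QualityError(
            f"{len(failed)}/{len(frames)} frames failed centerline extraction"
        )
    kymo = CurvatureKymograph(
        values=rows,
        frame_rate=frame_rate,
        body_length=float(np.nanmean(lengths)),
        body_lengths=lengths,
        failed_frames=failed,
    )
    head_first = assign_head_tail(kymo, override=None if head_end == "auto" else head_end)
    if not head_first:
        kymo.values = _flip_kymograph_values(kymo.values)
        centerlines = [
            Centerline(points=cl.points[::-1].copy(), frame_index=cl.frame_index)
            if cl is not None else None
            for cl in centerlines
        ]
    return kymo, centerlines
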