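"""Cross-correlation of bending and calcium traces and the signed peak statistic.

The correlogram holds the Pearson correlation at every integer-frame lag up
to +/- 20 s; positive lag means the response (calcium) follows the input
(bending).  Each lag's coefficient is computed over that lag's overlapping
window, mean-centered and variance-normalized there, so even edge lags are
bona fide correlations in [-1, 1]; missing frames are pairwise-deleted.

Group comparisons use the signed peak statistic: the lag of maximum absolute
mean correlation of a control group defines the reference time T_p, and each
recording contributes the coefficient of maximum magnitude (sign preserved)
within a 1 s window centered on T_p.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Union

import numpy as np

from .containers import BendingTrace, CrossCorrelogram, FluorescenceTrace
from .errors import ConfigurationError, DataError

__all__ = ["cross_correlate", "reference_peak", "peak_correlation"]


def _series(obj) -> np.ndarray:
    if isinstance(obj, BendingTrace):
        return obj.values
    if isinstance(obj, FluorescenceTrace):
        return obj.normalized if obj.normalized is not None else obj.raw
    return np.asarray(obj, dtype=float)


def _frame_rate(obj, fallback=None):
    fr = getattr(obj, "frame_rate", None)
    return fr if fr is not None else fallback


def cross_correlate(
    input_trace,
    response_trace,
    max_lag: float = 20.0,
    *,
    frame_rate: float = None,
    min_overlap: int = 3,
) -> CrossCorrelogram:
    """Pearson correlogram of two equally sampled series.

    Accepts :class:`BendingTrace` / :class:`FluorescenceTrace` (normalized
    values preferred) or plain arrays with an explicit ``frame_rate``.
    Lags with fewer than ``min_overlap`` valid pairs get NaN coefficients;
    a zero-variance overlap raises :class:`DataError`.
    """
    fr_in = _frame_rate(input_trace, frame_rate)
    fr_resp = _frame_rate(response_trace, frame_rate)
    if fr_in is None or fr_resp is None:
        raise ConfigurationError("frame_rate is required for plain arrays")
    if fr_in != fr_resp:
        raise ConfigurationError("input and response must share a frame rate")
    fs = float(fr_in)
    x = _series(input_trace)
    y = _series(response_trace)
    n = min(len(x), len(y))
    if len(x) != len(y):
        warnings.warn("traces differ in length; truncating to the overlap",
                      stacklevel=2)
        x, y = x[:n], y[:n]
    max_lag_frames = int(round(max_lag * fs))
    if n < 2 * max_lag_frames:
        warnings.warn(
            "trace shorter than twice the maximum lag; edge coefficients rest "
            "on short overlaps", stacklevel=2,
        )
    lags_f = np.arange(-max_lag_frames, max_lag_frames + 1)
    coeffs = np.full(len(lags_f), np.nan)
    for i, k in enumerate(lags_f):
        if k >= 0:
            xi, yi = x[: n - k] if k else x, y[k:]
        else:
            xi, yi = x[-k:], y[:n + k]
        m = np.isfinite(xi) & np.isfinite(yi)
        if m.sum() < min_overlap:
            continue
        xv, yv = xi[m], yi[m]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            raise DataError(f"zero-variance overlap window at lag {k / fs:.2f} s")
        coeffs[i] = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return CrossCorrelogram(
        lags=lags_f / fs,
        coefficients=coeffs,
        input_label=getattr(input_trace, "label", "") or "input",
        response_label=getattr(response_trace, "label", "") or "response",
    )


def reference_peak(correlograms: Sequence[CrossCorrelogram]) -> float:
    """T_p: the lag of maximum absolute mean coefficient of a control group.

    All correlograms must share a common lag grid.  Ties break toward the
    lag closest to zero.
    """
    if len(correlograms) == 0:
        raise DataError("empty collection of correlograms")
    lags = correlograms[0].lags
    for c in correlograms[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ConfigurationError("correlograms are not on a common lag grid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.stack([c.coefficients for c in correlograms]), axis=0)
    if not np.isfinite(mean).any():
        raise DataError("mean correlogram is all-missing")
    score = np.abs(np.nan_to_num(mean, nan=-np.inf))
    best = np.lexsort((np.abs(lags), -score))[0]
    return float(lags[best])


def peak_correlation(
    correlogram: CrossCorrelogram,
    t_p: float,
    window: float = 1.0,
) -> tuple:
    """Signed maximum-magnitude coefficient within [T_p - w/2, T_p + w/2].

    Returns ``(value, lag)``; the sign of the coefficient is preserved and
    ties break toward the lag nearest T_p.  The window must lie inside the
    correlogram's lag range.
    """
    lags = correlogram.lags
    half = window / 2.0
    eps = 1e-9
    if t_p - half < lags.min() - eps or t_p + half > lags.max() + eps:
        raise ConfigurationError("window extends beyond the correlogram lag range")
    sel = (lags >= t_p - half - eps) & (lags <= t_p + half + eps)
    c = correlogram.coefficients[sel]
    l = lags[sel]
    if not np.isfinite(c).any():
        raise DataError("all coefficients missing inside the peak window")
    score = np.abs(np.nan_to_num(c, nan=-np.inf))
    best = np.lexsort((np.abs(l - t_p), -score))[0]
    return float(c[best]), float(l[best])
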