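"""Bout kinematics and resistive-force-theory analysis of forward locomotion.

Resistive force theory (RFT) models the viscous force per unit length on a
slender undulating body as independent local drag along the tangential and
normal directions, with coefficients C_par and C_perp.  Thrust exists only
because C_perp > C_par; the single identifiable mechanical parameter is the
drag ratio K = C_perp / C_par.

For a body carrying a sinusoidal tangent-angle wave, force balance on an
infinite filament gives the small-angle propulsion efficiency

    eta = V_a / V_w = (K - 1) q / (1 + K q),        q = <psi^2>,

where <psi^2> is the mean squared angle between body segments and the
direction of motion.  Expressed through the angle of attack theta_a (the
mean *absolute* segment angle, so <psi^2> = (pi^2 / 8) theta_a^2 for a
sinusoidal profile):

    eta(theta_a; K) = (K - 1) (pi^2/8) theta_a^2 / (1 + K (pi^2/8) theta_a^2)

with theta_a in radians.  eta(0, K) = 0, eta(theta_a, 1) = 0, and eta grows
monotonically with theta_a.  The formula is certified against the numerical
force-balance oracle :func:`rft_force_balance`, which solves the full
zero-net-force / zero-net-torque problem for a finite body.

The drag-ratio fit follows the statsmodels shape: build a
:class:`DragRatioModel` from bout data, call :meth:`~DragRatioModel.fit`,
and read estimates and bootstrap uncertainties off the returned
:class:`DragRatioResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import Bout, Centerline, CurvatureKymograph
from .errors import ConfigurationError, DataError, FitError, WaveSpeedError

__all__ = [
    "segment_bouts",
    "actual_speed",
    "wave_speed",
    "angle_of_attack",
    "rft_efficiency_smallangle",
    "rft_force_balance",
    "ForceBalanceResult",
    "DragRatioModel",
    "DragRatioResults",
    "fit_drag_ratio",
    "bin_by_angle",
    "epoch_fractional_change",
    "bout_kinematics",
]

_Q_FACTOR = np.pi ** 2 / 8.0  # <psi^2> = _Q_FACTOR * theta_a^2 for sinusoidal psi


# ---------------------------------------------------------------------------
# small-angle closed form
# ---------------------------------------------------------------------------

def rft_efficiency_smallangle(theta_a_deg, K: float):
    """Small-angle RFT propulsion efficiency eta(theta_a; K).

    Parameters
    ----------
    theta_a_deg : float or array
        Angle of attack in degrees, 0 <= theta_a < 90.
    K : float
        Drag ratio C_perp / C_par, K > 0.  K = 1 (isotropic drag) gives
        zero efficiency at any angle.
    """
    theta = np.asarray(theta_a_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 90):
        raise ConfigurationError("theta_a must lie in [0, 90) degrees")
    if not K > 0:
        raise ConfigurationError("K must be > 0")
    q = _Q_FACTOR * np.radians(theta) ** 2
    eta = (K - 1.0) * q / (1.0 + K * q)
    if np.isscalar(theta_a_deg):
        return float(eta)
    return eta


# ---------------------------------------------------------------------------
# force-balance numerical oracle
# ---------------------------------------------------------------------------

@dataclass
class ForceBalanceResult:
    """Period-averaged kinematics of an RFT force-balance simulation."""

    v_a: float           # mm/s, mean forward speed (projection on net direction)
    v_w: float           # mm/s, prescribed wave speed in the worm frame
    efficiency: float    # v_a / v_w
    theta_a: float       # degrees, measured mean absolute segment angle
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))


def _wave_shape(amplitude: float, wavelength_fraction: float, frequency: float,
                body_length: float, n_points: int, t: float) -> np.ndarray:
    """Inextensible body-frame shape from the sinusoidal curvature wave at time t."""
    n_seg = n_points - 1
    s = (np.arange(n_seg) + 0.5) / n_seg
    kL = amplitude * np.sin(2 * np.pi * (frequency * t - s / wavelength_fraction))
    ds = 1.0 / n_seg
    psi = np.concatenate([[0.0], np.cumsum(kL * ds)])
    psi_mid = 0.5 * (psi[:-1] + psi[1:])
    psi_mid -= psi_mid.mean()
    step = ds * body_length
    x = np.concatenate([[0.0], np.cumsum(np.cos(psi_mid) * step)])
    y = np.concatenate([[0.0], np.cumsum(np.sin(psi_mid) * step)])
    pts = np.stack([x, y], axis=1)
    return pts - pts.mean(axis=0)


def rft_force_balance(
    K: float,
    *,
    curvature_amplitude: float = 1.0,
    wavelength_fraction: float = 0.25,
    frequency: float = 1.0,
    body_length: float = 1.0,
    n_points: int = 151,
    steps_per_period: int = 300,
    n_periods: int = 4,
    transient_periods: int = 1,
    shape_fn=None,
    wave_speed_mm_s: Optional[float] = None,
) -> ForceBalanceResult:
    """Integrate RFT force and torque balance for prescribed undulation.

    At each time step the local drag per unit length is
    ``f = -C_par (u . t) t - C_perp (u . n) n`` with ``u`` the lab-frame
    velocity of each body point.  The instantaneous rigid translation and
    rotation are the solution of the linear zero-net-force and
    zero-net-torque conditions; the trajectory is integrated over
    ``n_periods`` undulation periods and averaged after discarding
    ``transient_periods``.

    By default the prescribed kinematics are the sinusoidal curvature wave of
    :mod:`wormbend.synthetic`; a custom ``shape_fn(t) -> (n, 2)`` array of
    arclength-uniform body-frame positions may be supplied together with its
    worm-frame ``wave_speed_mm_s``.

    Note the default ``wavelength_fraction`` of 0.25 puts four wavelengths on
    the body: in that many-wavelength regime the finite body's lateral and
    yaw recoil is negligible and the simulation approaches the
    infinite-filament limit in which the small-angle closed form is derived.
    At worm-like single-wavelength kinematics recoil is substantial and
    efficiency falls well below the closed form (see the methods note).
    """
    if not K > 0:
        raise ConfigurationError("K must be > 0")
    if frequency == 0:
        raise ConfigurationError("frequency must be non-zero")
    if shape_fn is None:
        def shape_fn(t, _a=curvature_amplitude, _l=wavelength_fraction,
                     _f=frequency, _L=body_length, _n=n_points):
            return _wave_shape(_a, _l, _f, _L, _n, t)
        # negative frequency = tailward-originating wave; speed stays positive
        wave_speed_mm_s = wavelength_fraction * body_length * abs(frequency)
    elif wave_speed_mm_s is None:
        raise ConfigurationError("wave_speed_mm_s is required with a custom shape_fn")

    period = 1.0 / abs(frequency)
    dt = period / steps_per_period
    n_steps = n_periods * steps_per_period
    c_par, c_perp = 1.0, K

    X = np.zeros(2)
    phi = 0.0
    positions = np.empty((n_steps + 1, 2))
    positions[0] = X
    lab_shapes = []

    S_prev = shape_fn(0.0)
    n = len(S_prev)
    ds = 1.0 / (n - 1)
    for k in range(n_steps):
        t = k * dt
        S_next = shape_fn(t + dt)
        Sdot = (S_next - S_prev) / dt
        cph, sph = np.cos(phi), np.sin(phi)
        R = np.array([[cph, -sph], [sph, cph]])
        P = S_prev @ R.T                  # lab positions relative to X
        Vdef = Sdot @ R.T                 # lab deformation velocity
        tang = np.gradient(P, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        perp = np.stack([-P[:, 1], P[:, 0]], axis=1)

        def drag(u):
            ut = (u * tang).sum(axis=1)
            un = (u * nrm).sum(axis=1)
            return -(c_par * ut[:, None] * tang + c_perp * un[:, None] * nrm)

        M = np.empty((3, 3))
        b = np.empty(3)
        ex = np.tile([1.0, 0.0], (n, 1))
        ey = np.tile([0.0, 1.0], (n, 1))
        for j, ub in enumerate((ex, ey, perp)):
            fj = drag(ub)
            M[0, j] = fj[:, 0].sum() * ds
            M[1, j] = fj[:, 1].sum() * ds
            M[2, j] = (P[:, 0] * fj[:, 1] - P[:, 1] * fj[:, 0]).sum() * ds
        f0 = drag(Vdef)
        b[0] = -f0[:, 0].sum() * ds
        b[1] = -f0[:, 1].sum() * ds
        b[2] = -(P[:, 0] * f0[:, 1] - P[:, 1] * f0[:, 0]).sum() * ds
        try:
            sol = np.linalg.solve(M, b)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular force-balance system at t={t:.4f}s") from exc
        X = X + sol[:2] * dt
        phi = phi + sol[2] * dt
        positions[k + 1] = X
        if k >= transient_periods * steps_per_period and k % 5 == 0:
            lab_shapes.append(P + X)
        S_prev = S_next

    i0 = transient_periods * steps_per_period
    disp = positions[-1] - positions[i0]
    T = (n_steps - i0) * dt
    v_a = float(np.linalg.norm(disp) / T)
    if v_a > 0:
        direction = disp / np.linalg.norm(disp)
    else:
        direction = np.array([1.0, 0.0])
    angles = []
    for P in lab_shapes:
        tg = np.diff(P, axis=0)
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        cosang = np.abs(tg @ direction)
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    theta_a = float(np.mean(angles)) if angles else float("nan")
    return ForceBalanceResult(
        v_a=v_a,
        v_w=float(wave_speed_mm_s),
        efficiency=v_a / float(wave_speed_mm_s),
        theta_a=theta_a,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# bout segmentation and kinematics
# ---------------------------------------------------------------------------

def segment_bouts(
    kymograph: CurvatureKymograph,
    track: Optional[np.ndarray] = None,
    min_duration: float = 10.0,
    *,
    reversal_flags: Optional[np.ndarray] = None,
    turn_threshold: float = np.pi / 2,
) -> list:
    """Maximal contiguous runs of forward frames of at least ``min_duration``.

    A frame is excluded when its curvature row is missing, when the absolute
    mean whole-body curvature exceeds ``turn_threshold`` (a turn), or when it
    is flagged as a reversal by the caller.  Returns an empty list with a
    warning when no run qualifies.
    """
    T = kymograph.n_frames
    if track is not None:
        track = np.asarray(track, dtype=float)
        if len(track) != T:
            raise ConfigurationError("track and kymograph must share the time base")
    bad = ~np.isfinite(kymograph.values).all(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_k = np.nanmean(kymograph.values, axis=1)
    bad |= np.abs(np.nan_to_num(mean_k, nan=np.inf)) > turn_threshold
    if reversal_flags is not None:
        flags = np.asarray(reversal_flags, dtype=bool)
        if len(flags) != T:
            raise ConfigurationError("reversal_flags length must match kymograph frames")
        bad |= flags
    min_frames = max(2, int(round(min_duration * kymograph.frame_rate)))
    bouts = []
    start = None
    for i in range(T + 1):
        good = i < T and not bad[i]
        if good and start is None:
            start = i
        elif not good and start is not None:
            if i - start >= min_frames:
                bouts.append(Bout(start=start, stop=i, frame_rate=kymograph.frame_rate))
            start = None
    if not bouts:
        warnings.warn("no qualifying forward bout found", stacklevel=2)
    return bouts


def actual_speed(bout: Bout, track: np.ndarray) -> float:
    """Net centroid displacement over the bout projected on its mean direction.

    The mean direction of motion is the unit vector of the net displacement,
    so this equals net displacement magnitude divided by bout duration.
    """
    track = np.asarray(track, dtype=float)
    if bout.n_frames < 2:
        raise ConfigurationError("bout must span at least 2 frames")
    disp = track[bout.stop - 1] - track[bout.start]
    return float(np.linalg.norm(disp) / bout.duration)


def _dominant_frequency(X: np.ndarray, frame_rate: float) -> tuple:
    """Dominant temporal frequency of a multichannel signal via an
    interpolated Hann periodogram.  Returns (f0, wave_power_fraction)."""
    T = X.shape[0]
    win = np.hanning(T)
    Xw = (X - X.mean(axis=0)) * win[:, None]
    nfft = 4 * T
    F = np.fft.rfft(Xw, n=nfft, axis=0)
    power = (np.abs(F) ** 2).sum(axis=1)
    power[0] = 0.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame_rate)
    i = int(np.argmax(power))
    if 0 < i < len(power) - 1 and power[i] > 0:
        lm, l0, lp = np.log(power[i - 1] + 1e-300), np.log(power[i] + 1e-300), np.log(power[i + 1] + 1e-300)
        denom = lm - 2 * l0 + lp
        delta = 0.5 * (lm - lp) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f0 = float(freqs[i] + delta * (freqs[1] - freqs[0]))
    # fraction of total variance concentrated near the peak (+/- 2 native bins)
    native_bin = 4  # padded bins per native bin
    lo = max(1, i - 2 * native_bin)
    hi = min(len(power), i + 2 * native_bin + 1)
    frac = float(power[lo:hi].sum() / power[1:].sum()) if power[1:].sum() > 0 else 0.0
    return f0, frac


def _phase_slope(values: np.ndarray, frame_rate: float, min_coherence: float = 0.5):
    """Phase of each body segment at the dominant frequency, and the fitted
    slope d(phase)/d(body fraction).  Raises WaveSpeedError when incoherent.

    Returns (f0, slope_rad_per_body, fit_r2).
    """
    X = values[np.isfinite(values).all(axis=1)]
    if X.shape[0] < 5:
        raise WaveSpeedError("too few valid frames for wave analysis")
    if np.allclose(X.std(axis=0), 0):
        raise WaveSpeedError("kymograph has no temporal variation")
    f0, frac = _dominant_frequency(X, frame_rate)
    if f0 <= 0 or frac < 0.2:
        raise WaveSpeedError(
            f"no coherent oscillation (spectral peak fraction {frac:.2f} < 0.2)"
        )
    T = X.shape[0]
    t = np.arange(T) / frame_rate
    carrier = np.exp(-2j * np.pi * f0 * t)
    win = np.hanning(T)
    Z = ((X - X.mean(axis=0)) * (carrier * win)[:, None]).sum(axis=0)
    phase = np.unwrap(np.angle(Z))
    n_seg_total = values.shape[1]
    s = (np.arange(n_seg_total) + 0.5) / n_seg_total
    A = np.stack([s, np.ones_like(s)], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, phase, rcond=None)
    fitted = A @ coef
    ss_tot = np.sum((phase - phase.mean()) ** 2)
    r2 = 1.0 - np.sum((phase - fitted) ** 2) / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_coherence:
        raise WaveSpeedError(f"phase profile is not linear along the body (R^2 {r2:.2f})")
    return f0, float(coef[0]), float(r2)


def wave_speed(
    kymograph: CurvatureKymograph,
    bout: Optional[Bout] = None,
    *,
    segment_range: tuple = (20, 80),
    min_coherence: float = 0.5,
) -> float:
    """Phase speed of the curvature wave along the body, in mm/s.

    The per-segment phase of the dominant oscillation frequency is fitted
    linearly against body coordinate (segments ``segment_range`` only, to
    avoid head/tail edge noise); the slope gives the wavelength and, with the
    dominant frequency, the worm-frame wave speed ``V_w = lambda * f``.
    Positive sign means head-to-tail propagation.
    """
    vals = kymograph.values
    if bout is not None:
        vals = vals[bout.start:bout.stop]
    lo, hi = segment_range
    lo = max(0, lo)
    hi = min(kymograph.n_segments, hi)
    sub = vals[:, lo:hi]
    f0, slope_sub, _ = _phase_slope(sub, kymograph.frame_rate, min_coherence)
    # _phase_slope fits phase against the sub-array's own fractional coordinate;
    # one unit of that coordinate spans (hi - lo)/n_segments of the body
    slope_body = slope_sub / ((hi - lo) / kymograph.n_segments)
    wavelength_fraction = 2 * np.pi / abs(slope_body)
    sign = -np.sign(slope_body)  # phase decreasing tailward = head->tail travel
    return float(sign * wavelength_fraction * kymograph.body_length * f0)


def angle_of_attack(
    centerlines: Sequence[Centerline],
    direction: np.ndarray,
    *,
    segment_range: Optional[tuple] = None,
) -> float:
    """Mean absolute acute angle (degrees) between body segments and the
    direction of forward motion, averaged over frames and segments."""
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise DataError("direction of motion is undefined (zero net displacement)")
    d = d / nd
    angles = []
    for cl in centerlines:
        tg = np.diff(cl.points, axis=0)
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        if segment_range is not None:
            tg = tg[segment_range[0]:segment_range[1]]
        cosang = np.abs(tg @ d)
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    if not angles:
        raise DataError("no centerlines supplied")
    return float(np.mean(angles))


def bout_kinematics(
    bout: Bout,
    kymograph: CurvatureKymograph,
    track: np.ndarray,
    centerlines: Optional[Sequence[Centerline]] = None,
    *,
    head_fraction: float = 0.18,
) -> Bout:
    """Fill V_a, V_w, theta_a, efficiency and head amplitude on a bout."""
    track = np.asarray(track, dtype=float)
    bout.v_a = actual_speed(bout, track)
    bout.v_w = abs(wave_speed(kymograph, bout))
    bout.efficiency = bout.v_a / bout.v_w if bout.v_w > 0 else np.nan
    if centerlines is not None:
        disp = track[bout.stop - 1] - track[bout.start]
        cls = [cl for cl in centerlines if bout.start <= cl.frame_index < bout.stop]
        bout.theta_a = angle_of_attack(cls, disp)
    n_head = int(round(head_fraction * kymograph.n_segments))
    head = np.nanmean(kymograph.values[bout.start:bout.stop, :n_head], axis=1)
    head = head[np.isfinite(head)]
    bout.head_amplitude = float(head.std()) if head.size else np.nan
    return bout


# ---------------------------------------------------------------------------
# drag-ratio fit (Model / Results)
# ---------------------------------------------------------------------------

class DragRatioModel:
    """Least-squares fit of the drag ratio K to (theta_a, efficiency) bouts.

    Minimizes ``sum_i (efficiency_i - eta(theta_a_i; K))^2`` over K > 1 with
    the small-angle efficiency curve.  Bouts with theta_a above ``theta_cap``
    (outside the small-angle validity, default 60 degrees) are excluded.

    Examples
    --------
    >>> model = DragRatioModel(efficiency, theta_a_deg)
    >>> res = model.fit(n_boot=1000, seed=0)
    >>> res.K, res.bse
    """

    K_MAX = 50.0

    def __init__(self, efficiency, theta_a_deg, *, theta_cap: float = 60.0):
        eff = np.asarray(efficiency, dtype=float)
        theta = np.asarray(theta_a_deg, dtype=float)
        if eff.shape != theta.shape or eff.ndim != 1:
            raise ConfigurationError("efficiency and theta_a_deg must be equal-length 1-D")
        keep = np.isfinite(eff) & np.isfinite(theta) & (theta <= theta_cap)
        self.efficiency = eff[keep]
        self.theta_a_deg = theta[keep]
        self.theta_cap = theta_cap
        if len(self.efficiency) < 3:
            raise DataError("at least 3 bouts within the small-angle cap are required")

    @classmethod
    def from_dataframe(cls, bouts: pd.DataFrame, *, efficiency_col: str = "efficiency",
                       theta_col: str = "theta_a_deg", **kwargs) -> "DragRatioModel":
        return cls(bouts[efficiency_col].to_numpy(), bouts[theta_col].to_numpy(), **kwargs)

    def _ssr(self, K: float) -> float:
        eta = rft_efficiency_smallangle(self.theta_a_deg, K)
        return float(np.sum((self.efficiency - eta) ** 2))

    def _solve(self, eff: np.ndarray, theta: np.ndarray) -> float:
        q = _Q_FACTOR * np.radians(theta) ** 2

        def ssr(K):
            eta = (K - 1.0) * q / (1.0 + K * q)
            return float(np.sum((eff - eta) ** 2))

        res = minimize_scalar(ssr, bounds=(1.0, self.K_MAX), method="bounded",
                              options={"xatol": 1e-10})
        if not res.success:
            raise FitError(f"drag-ratio fit did not converge: {res.message}")
        return float(res.x)

    def fit(self, *, n_boot: int = 1000, seed: Optional[int] = None) -> "DragRatioResults":
        K_hat = self._solve(self.efficiency, self.theta_a_deg)
        boot = None
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            n = len(self.efficiency)
            boot = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                boot[b] = self._solve(self.efficiency[idx], self.theta_a_deg[idx])
        return DragRatioResults(model=self, K=K_hat, bootstrap=boot)


@dataclass
class DragRatioResults:
    """Estimated drag ratio with residual diagnostics and bootstrap uncertainty."""

    model: DragRatioModel
    K: float
    bootstrap: Optional[np.ndarray] = None

    @property
    def params(self) -> dict:
        return {"K": self.K}

    @property
    def fittedvalues(self) -> np.ndarray:
        return rft_efficiency_smallangle(self.model.theta_a_deg, self.K)

    @property
    def resid(self) -> np.ndarray:
        return self.model.efficiency - self.fittedvalues

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid ** 2))

    @property
    def n_bouts(self) -> int:
        return len(self.model.efficiency)

    @property
    def bse(self) -> Optional[float]:
        """Bootstrap standard error of K."""
        if self.bootstrap is None:
            return None
        return float(np.std(self.bootstrap, ddof=1))

    def conf_int(self, alpha: float = 0.05) -> Optional[tuple]:
        """Percentile bootstrap confidence interval for K."""
        if self.bootstrap is None:
            return None
        lo, hi = np.percentile(self.bootstrap, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)

    @property
    def at_boundary(self) -> bool:
        """True when the estimate collapsed to the isotropic-drag boundary K = 1."""
        return self.K - 1.0 < 1e-6

    @property
    def c_perp_over_c_par(self) -> float:
        return self.K

    def plot(self, ax=None):
        """Scatter the bouts with the fitted efficiency curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.theta_a_deg, m.efficiency, "k.", alpha=0.6, label="bouts")
        grid = np.linspace(0.0, min(m.theta_cap, 89.0), 200)
        ax.plot(grid, rft_efficiency_smallangle(grid, self.K), "m-",
                label=f"RFT fit, $C_\\perp/C_\\parallel$ = {self.K:.2f}")
        ax.set_xlabel("angle of attack $\\theta_a$ (deg)")
        ax.set_ylabel("propulsion efficiency $V_a/V_w$")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = [
            "Drag-ratio fit (small-angle RFT efficiency curve)",
            "=" * 50,
            f"n bouts            : {self.n_bouts}",
            f"theta_a cap        : {self.model.theta_cap:.1f} deg",
            f"K = C_perp/C_par   : {self.K:.4f}",
        ]
        if self.bse is not None:
            ci = self.conf_int()
            lines.append(f"bootstrap SE       : {self.bse:.4f}  (n={len(self.bootstrap)})")
            lines.append(f"95% CI             : [{ci[0]:.4f}, {ci[1]:.4f}]")
        lines.append(f"SSR                : {self.ssr:.6g}")
        if self.at_boundary:
            lines.append("warning            : estimate at isotropic boundary K -> 1")
        return "\n".join(lines)


def fit_drag_ratio(bouts: pd.DataFrame, *, theta_cap: float = 60.0,
                   n_boot: int = 1000, seed: Optional[int] = None) -> DragRatioResults:
    """Convenience wrapper: fit K from a bout table with columns
    ``theta_a_deg`` and ``efficiency``."""
    return DragRatioModel.from_dataframe(bouts, theta_cap=theta_cap).fit(
        n_boot=n_boot, seed=seed
    )


# ---------------------------------------------------------------------------
# binning and epoch comparison
# ---------------------------------------------------------------------------

def bin_by_angle(bouts: pd.DataFrame, bin_width: float = 5.0) -> pd.DataFrame:
    """Mean +/- SEM of V_a and V_w in angle-of-attack bins.

    Expects columns ``theta_a_deg``, ``v_a`` and ``v_w``.  Bins with a single
    bout report the SEM as missing; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be > 0")
    df = bouts.dropna(subset=["theta_a_deg"])
    idx = np.floor(df["theta_a_deg"] / bin_width).astype(int)
    rows = []
    for b, grp in df.groupby(idx):
        def _sem(x):
            x = x.dropna()
            return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        rows.append({
            "bin_center": (b + 0.5) * bin_width,
            "va_mean": grp["v_a"].mean(),
            "va_sem": _sem(grp["v_a"]),
            "vw_mean": grp["v_w"].mean(),
            "vw_sem": _sem(grp["v_w"]),
            "n": len(grp),
        })
    return pd.DataFrame(rows).sort_values("bin_center").reset_index(drop=True)


def epoch_fractional_change(
    bouts_pre: pd.DataFrame,
    bouts_during: pd.DataFrame,
    metric: str = "v_a",
) -> float:
    """Per-trial fractional change ``(mean_during - mean_pre) / mean_pre``.

    ``metric`` is ``"v_a"`` or ``"efficiency"``.  Suitable for export and a
    zero-median sign/rank test across trials.
    """
    if metric not in ("v_a", "efficiency"):
        raise ConfigurationError("metric must be 'v_a' or 'efficiency'")
    if len(bouts_pre) == 0 or len(bouts_during) == 0:
        raise DataError("both epochs must contain at least one bout")
    pre = float(bouts_pre[metric].mean())
    dur = float(bouts_during[metric].mean())
    if pre == 0:
        raise DataError("pre-epoch mean is zero; fractional change undefined")
    return (dur - pre) / pre
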