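# Methods

This note documents the models, estimators and numerical choices behind
wormbend, and what the synthetic-data tests do and do not establish about
real recordings.

## Posture model and curvature estimation

A single worm is modeled as an inextensible planar curve of length L with a
half-width profile w(s), s ∈ [0, 1] the body coordinate from the nose tip.
Curvature is reported body-length-normalized (κ·L, dimensionless) because it
is then invariant to animal size and magnification; ventral bending is
positive (the dorsoventral side cannot be inferred from a silhouette and is
supplied as metadata, `ventral_sign`).

**Binarization** thresholds each frame (Otsu by default, or a fixed
threshold), keeps the largest connected component and fills holes.

**Head/tail detection.** The silhouette boundary is resampled to uniform
arclength (400 samples) and smoothed with a circular moving average over 2%
of the perimeter.  Candidate tips are local maxima of the *windowed turning
angle*: the integral of convex boundary curvature over a window of 4% of
the perimeter.  A body cap turns through ≈ π radians inside that window,
whereas any smooth bend of the body — even the outer apex of a U-shaped
posture — accumulates well under half a radian, and single-pixel curvature
spikes integrate to almost nothing.  Peaks must exceed 1.2 rad and lie at
least 25% of the perimeter apart; a near-circular blob therefore has no
qualifying peak and raises an error rather than returning nonsense.  The
peak only localizes a blunt cap to about the window width, so the tip is
refined to the cap point most distal from the local shoulder region.

**Centerline.** The boundary (800 samples for this step) is split at the
two tips into two flanks.  Plain arclength-fraction matching of flank
points mispairs them wherever the body bends, because the inner and outer
boundaries advance at local rates (1 ∓ w·κ) relative to the midline; the
resulting midline wobbles at harmonics of the bending wave.  wormbend
therefore reweights the flank parameterizations by those rates and
re-averages (two fixed-point iterations), then resamples the midline to 101
equally spaced points.  A midline that leaves the mask (coiled,
self-touching postures) triggers a skeleton-path fallback and, failing
that, the frame is dropped and flagged — never guessed.

**Curvature.** The unwrapped tangent angle ψ(s) of the 100 segments is
low-pass filtered along the body with a zero-phase 4th-order Butterworth at
4 cycles/body (config key `smoothing_cutoff`).  Undulation carries at most
~2.5 spatial cycles (wavelength ≥ 0.4 L), where the filter's passband is
flat to < 0.2%, while pixel-scale boundary noise is strongly suppressed; a
quadratic-penalty smoothing spline was rejected because suppressing the
same noise attenuated the signal band by 2–5%.  Filter end handling
matters as much as the filter: ψ is extended beyond both ends before
filtering, first by quadratic extrapolation and then, in a second pass, by
an autoregressive (AR-8) continuation fitted to the first pass's smooth
interior, which follows an undulatory tangent angle past the tips instead
of bending it flat.  `filtfilt` uses odd reflection beyond the explicit
pads so that constant curvature (linear ψ) passes through exactly.
Curvature is the derivative dψ/d(s/L), directly κ·L.

**Head/tail orientation** is automatic: the head is the end whose curvature
phase leads (the wave travels head → tail in forward locomotion), read off
the sign of the along-body phase slope at the dominant frequency.  A static
worm or an incoherent kymograph raises an orientation error prompting
manual assignment (`head_end='first'|'last'`).

On rendered noise-free test movies (1 mm worm at 0.004 mm/px, κ·L
amplitude 3, 1 Hz wave sampled at 5 Hz) the full pipeline recovers the
generator kymograph with ≈ 5% normalized RMSE, limited by the ~1% of body
length near each tip that a silhouette cannot resolve and by residual
pixel-scale boundary noise.

## Head-bending statistics

The head region is the anterior 18 of 100 segments (`head_fraction` 0.18);
the head curvature trace is their per-frame mean, with missing frames
propagated as NaN.  The head-bending amplitude is the *population* standard
deviation of that trace over the measurement — a descriptive statistic of
the full measured lapse, not an estimate from a sample — and requires at
least 150 valid frames (30 s at 5 Hz) by default.  For microfluidic
recordings where only the head moves, bending is read out as the
orientation of the second-moment ellipse of the head ROI, unwrapped with
period π to avoid ±90° jumps, referenced to the minimum-bending frame
(automatically the frame closest to the median orientation) and normalized
by the maximum deflection to an index in [−1, 1], ventral positive.

## Calcium traces and cross-correlation

ROI intensity is the sum of (pixel − background) over the ROI, with the
background estimated as the mean of a user-drawn background region (the
deterministic manual workflow; no photobleaching detrend by default).
Normalization is (F − F_min)/(F_max − F_min) per recording, which is
invariant under positive affine rescaling — so exposure and gain drop out —
and a GCaMP/RFP ratio is available to cancel motion and expression
artifacts common to both channels.

Cross-correlograms hold the Pearson coefficient at every integer-frame lag
up to ±20 s, positive lag meaning the calcium response follows the bending
input.  Each lag's coefficient is centered and variance-normalized over
that lag's own overlap window (missing frames pairwise-deleted), so even
edge lags are genuine correlations in [−1, 1]; because Pearson correlation
is affine-invariant, the choice of per-individual normalization upstream
cannot affect the coefficients.  The group statistic is the signed
coefficient of maximum magnitude within a closed 1 s window (5 lags at
5 Hz) centered on the reference peak T_p, the lag of the maximum absolute
mean control-group correlation; ties break toward the lag nearest T_p.

One caveat the synthetic tests make explicit: for a perfectly periodic
noise-free sinusoid the peak lag is only defined modulo the undulation
period, and every period-shifted peak is equivalent.  Real undulation is
irregular; the generator reproduces this with curvature noise, which makes
the true lag the unique global maximum.

## Resistive force theory

RFT models the viscous force per unit length on a slender body as local
anisotropic drag, f = −C∥(u·t̂)t̂ − C⊥(u·n̂)n̂.  Thrust requires C⊥ > C∥ and
only the ratio K = C⊥/C∥ is identifiable from kinematics.

**Small-angle closed form.**  For an infinite filament carrying a
sinusoidal tangent-angle wave ψ of amplitude ψ₀, integrating the
longitudinal force balance gives

η = V_a/V_w = (K − 1)⟨ψ²⟩ / (1 + K⟨ψ²⟩).

Expressed through the angle of attack θ_a = ⟨|ψ|⟩ = (2/π)ψ₀ (so
⟨ψ²⟩ = (π²/8)θ_a²):

η(θ_a; K) = (K − 1)(π²/8)θ_a² / (1 + K(π²/8)θ_a²),  θ_a in radians.

η(0, K) = 0, η(θ_a, 1) ≡ 0, and η increases monotonically with θ_a.

**Force-balance oracle.** `rft_force_balance` integrates the full problem
for a finite body with prescribed curvature-wave kinematics: at each time
step the instantaneous rigid translation and rotation solve the linear
zero-net-force and zero-net-torque conditions, the trajectory is integrated
over 4 undulation periods (300 steps each) and averaged after discarding
one transient period.  With isotropic drag (K = 1) the centroid is
stationary to machine precision.  The oracle certifies the closed form in
the regime where its assumptions hold: with four wavelengths on the body
(wavelength fraction 0.25) and θ_a ≤ 15°, formula and simulation agree
within 2.7% over K ∈ [1.2, 2.0].  At worm-like single-wavelength
kinematics the finite body recoils — force and torque balance induce
lateral and yaw oscillations the infinite-filament derivation neglects —
and the simulated efficiency falls ~45% below the closed form even at small
angles.  The curve fitted to bout data is therefore an effective small-angle
law, exactly as it is used on experimental bouts.

**Bout kinematics.** Bouts are maximal runs of forward frames (missing
rows, turn frames with |mean body κ·L| > π/2, and externally flagged
reversals excluded) of at least 10 s.  V_a is the net centroid displacement
projected on the bout's mean direction of motion (the unit vector of the
net displacement; per-frame directions are contaminated by head swings)
divided by duration.  V_w comes from the kymograph: the per-segment phase
of the dominant temporal frequency (interpolated Hann periodogram) is fitted
linearly against body coordinate over segments 20–80 (avoiding head/tail
edge noise); the slope gives the wavelength, and V_w = λ·f·L.  The fit is
rejected — wave-speed error — when the spectral peak holds < 20% of the
variance or the phase profile is not linear (R² < 0.5), so white noise or a
static worm cannot produce a speed.  θ_a averages the absolute acute angle
between segment tangents and the direction of motion over frames and all
100 segments (a trim option exists).

**Drag-ratio fit.** `DragRatioModel` minimizes Σ(η_i − η(θ_i; K))² over
K ∈ (1, 50] by bounded scalar minimization (xatol 10⁻¹⁰; noise-free closure
recovers K to better than 4 significant digits).  Bouts above a 60°
small-angle cap are excluded.  Uncertainty is a case-resampling bootstrap
(default 1000 resamples) because the curve is nonlinear in K and residuals
are heteroscedastic after truncation at η ≥ 0; an estimate collapsing to
the K → 1 boundary (e.g. all-zero efficiencies) is flagged rather than
reported as converged.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions the analysis targets: a
dorsoventral curvature wave κ·L(s, t) = A sin(2πft − 2πs/λ) traveling head
to tail (defaults A = 3, f = 1 Hz, λ = 1 body length — a worm-like crawling
gait), imaged as an 8-bit binary silhouette at 5 Hz; GCaMP-like traces
F = baseline + gain·max(±κ_head(t − lag), 0) + noise, half-wave rectified
because the dorsal and ventral neuron classes respond to opposite bending
directions (the rectified-linear coupling is a stand-in, not a mechanistic
claim); and bout tables drawn from the small-angle efficiency curve with
truncated Gaussian noise (efficiency is a speed ratio of forward bouts, so
negative draws are clipped to zero).  Every randomized generator is a pure
function of its seed.

The rendered body is the union of discs along the midline with half-width
w(s) = L(0.0035 + 0.0365 sin πs): maximal half-width 0.04 L mid-body and a
blunt 3.5 µm tip on a 1 mm animal.  Real worm tips are blunt, and a
strictly positive tip width keeps the whole body above the pixel scale of a
realistic recording (0.004 mm/px default); with a width that tapers to
zero, the outer ~1.5% of the body is invisible to *any* tracker and the
recovered body coordinate is compressed accordingly.  Discs narrower than
half a pixel are skipped during rasterization (they could only produce
isolated specks), and rendering refuses masks that touch the image margin
or disconnect.

Passing the synthetic closure tests shows the pipeline is internally
consistent — geometry in, geometry out — under realistic sampling and
pixelation.  It does not exercise uneven illumination, motion blur,
overlapping tracks, omega turns or coiling (coiled frames are dropped, not
untangled), stage-motion registration, or real fluorescence statistics
(photon noise, bleaching, z-drift); conclusions about those require real
recordings.

## Problem sizes and runtimes

Test and acceptance runs use 50–150-frame movies at 384×384 px, 100-seed
replicate sets for the drag-ratio recovery, and 240–300 steps per period
for the force-balance oracle — sizes at which every check completes in
seconds while the statistics (closure NRMSE ≈ 5%, recovery rate ≥ 90%) are
already stable.  The full test suite runs in well under a minute.

## Known limitations

* The body coordinate of a tracked worm is its own measured arclength; a
  ~1% compression from unresolvable tip geometry is inherent to silhouette
  tracking and appears as a small coherent bias near the tips.
* Head/tail orientation requires a propagating wave; recordings of
  stationary animals need the manual override.
* The V_w estimator assumes a single coherent wave; multi-frequency gaits
  (e.g. transitional swimming) would need a time-resolved extension.
* The small-angle efficiency curve ignores finite-length recoil (see
  above); fitted K values are effective parameters of that curve, which is
  how the curve is applied to experimental data it is compared against.
* No multi-worm scenes, no fluid simulation in the image generator
  (translation is kinematic), no agar/liquid rheology beyond the drag
  ratio.
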