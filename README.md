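# wormbend

Quantitative analysis of *C. elegans* head-bending behavior and undulatory
locomotion: worm posture and curvature extraction from binary movies,
head-bend amplitude statistics, calcium–behavior cross-correlation, and a
resistive-force-theory (RFT) analysis linking the angle of attack to
propulsion efficiency, including drag-ratio fitting.  A synthetic-data
module generates worm movies, calcium traces and locomotion bouts with
known ground truth, so every stage of the pipeline is testable end to end
without any recordings.

The package is aimed at worm-behavior labs quantifying how neural
modulation of head bending shapes forward locomotion, and at anyone who
needs a tested, scriptable single-worm curvature pipeline.

## What it computes

**Posture.** Each binarized frame is reduced to a 101-point centerline
(head at index 0); head and tail are the two sharpest convex features of
the silhouette boundary, and head/tail orientation is assigned
automatically from the direction the bending wave travels.  Curvature is
stored body-length-normalized (the dimensionless κ·L), ventral bending
positive, as a time × 100-segment *curvature kymograph* — the central
intermediate of the whole analysis.

**Head bending.** The head curvature is the mean of the first 18 of 100
segments, and the *head-bending amplitude* is the population standard
deviation of that trace over the measurement (≥ 150 frames at 5 Hz).  For
head-restrained (microfluidic) recordings, an ellipse-orientation bending
index in [−1, 1] is provided instead.

**Calcium coupling.** ROI fluorescence is background-subtracted, normalized
per recording to (F − F_min)/(F_max − F_min), and cross-correlated with the
bending trace at every frame lag up to ±20 s.  Group comparisons use the
signed peak statistic: the coefficient of maximum magnitude within a 1 s
window centered on the control group's peak lag T_p.

**Locomotion and RFT.** For each bout of forward locomotion (~10–15 s,
reversal and turn frames excluded) the pipeline measures the actual
centroid speed V_a, the undulation wave speed V_w (from the phase slope of
the kymograph along the body), the angle of attack θ_a (mean absolute angle
between body segments and the direction of motion), and the propulsion
efficiency η = V_a / V_w.  Resistive force theory for a slender undulator
predicts, in the small-angle limit,

    η(θ_a; K) = (K − 1) q / (1 + K q),      q = (π²/8) θ_a²  (θ_a in radians)

where K = C⊥/C∥ is the ratio of the normal to the tangential drag
coefficient — the single identifiable mechanical parameter (K = 1, isotropic
drag, gives no propulsion).  `DragRatioModel.fit()` estimates K from bout
data by least squares with bootstrap uncertainties, and
`rft_force_balance()` provides an independent numerical oracle that solves
the full zero-net-force/zero-net-torque problem for prescribed undulation.

## Worked example

```python
import wormbend as wb
from wormbend.posture import build_kymograph
from wormbend.headbend import head_curvature, head_bending_amplitude
from wormbend import rft

# a 30 s synthetic crawl: 1 Hz wave, amplitude kappa*L = 3, 5 Hz imaging
params = wb.WaveParams(curvature_amplitude=3.0, duration=30.0,
                       frame_rate=5.0, seed=42)
frames, truth = wb.make_synthetic_movie(params, image_shape=(384, 384),
                                        mm_per_px=0.004)

kymo, centerlines = build_kymograph(frames)
amp = head_bending_amplitude(head_curvature(kymo), min_frames=150)
print(f"head bend amplitude : {amp:.3f} (kappa*L units)")
print(f"wave speed V_w      : {rft.wave_speed(kymo):.3f} mm/s")

bouts = wb.make_rft_bouts(K_true=1.6, n_bouts=100, theta_range=(5, 45),
                          efficiency_noise_sd=0.05, seed=0)
res = wb.fit_drag_ratio(bouts, n_boot=1000, seed=0)
print(res.summary())
```

prints

```
head bend amplitude : 2.020 (kappa*L units)
wave speed V_w      : 0.998 mm/s
Drag-ratio fit (small-angle RFT efficiency curve)
==================================================
n bouts            : 100
theta_a cap        : 60.0 deg
K = C_perp/C_par   : 1.5787
bootstrap SE       : 0.0249  (n=1000)
95% CI             : [1.5286, 1.6285]
SSR                : 0.193957
```

The head-bend amplitude 2.020 is the time SD of the anterior-18-segment
curvature: for this wave the analytic value is 2.010, recovered through
rendering and tracking to within 0.5%.  The wave speed matches the
generator's λ·f = 1 mm/s.  The drag-ratio fit recovers the generating
K = 1.6 within its bootstrap confidence interval from 100 noisy bouts.

A command-line interface mirrors the library:

```bash
wormbend simulate --out sim/ --seed 1
wormbend track --in sim/movie.tif --px-size 0.005 --frame-rate 5 --out kymo.csv
wormbend bend --kymo kymo.csv --min-frames 150 --out amplitude.csv
wormbend rft --kymo kymo.csv --track kymo_track.csv --min-bout 10 --fit --out bouts.csv
wormbend run --stages simulate,track,bend,rft --out run1/ --seed 1
```

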