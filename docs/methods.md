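# Methods

This note records the models, parameter choices and numerical decisions
behind `qome`, and what the synthetic-data validation does and does not
establish.

## Signals and conventions

Recordings are triaxial accelerometer (m/s², gravity-inclusive) and
gyroscope (deg/s) series sampled uniformly at 52.6 Hz. The sensor frame
follows the pronated-horizontal convention: +X posterior, +Y medial,
+Z vertical, so a static device with its z axis up reads
a = (0, 0, −9.81) m/s². The tilt angle Θ = arccos(−a_z/‖a‖) is then 0°
for a hanging-down orientation of the device z axis and 95° is a typical
resting forearm posture. Tilt is computed from *raw* acceleration: the
formula estimates the projection of gravity, and applying it to
gravity-subtracted acceleration would be meaningless. Samples with
‖a‖ below 0.5 m/s² are flagged invalid rather than raising.

## Gravity removal

An IMU-variant Madgwick complementary filter (gradient-descent
accelerometer correction at rate β = 0.1 rad/s on top of gyro
integration) tracks the gravity direction; linear acceleration is the
raw signal minus the rotated gravity vector. The quaternion is
initialized from the first accelerometer sample (shortest-arc alignment),
so a static sensor is converged immediately; we still require ≥ 5 s of
data, the window after which we hold the static residual to be below
0.1 m/s². The sequential kernel is numba-compiled with a pure
NumPy/Python fallback.

Validation gives: static residual ≈ 0; exact-rate rotations tracked to
< 0.3°; a 2.5 m/s², 1.5 Hz injected sinusoid recovered within ~2% by
quadrature projection. During movement bursts the accelerometer
direction is corrupted by linear acceleration, and the β-rate correction
leaks a small oscillatory error into the gravity estimate — at the
default β this is below 10% of burst amplitude, which is why β is not
exposed as a tuning target.

## Inactivity filter

u_t = 1 where ‖linear accel‖ > θ_u·9.81 (θ_u in G); U_t is the *trailing*
mean of u over round(D·fs) samples (the defining integral runs over
[t−D, t]; partial windows at the start use the available samples);
keep where U_t ≥ θ_U. Defaults θ_u = 0.1 G, θ_U = 0.10, D = 10 s.
Non-wear is removed first: maximal runs in which all six channels stay
constant (within a tolerance, default exact) longer than 180 s.
The threshold grid search evaluates the 6 × 6 grid over [0.05, 0.30]²
(step 0.05 — the grid range is prescribed, the step is our choice),
computes each pair's per-subject inactive fraction and its Pearson
correlation with UEFM (two-sided test, α = 0.05), and among significant
pairs returns the one that retains the most data (ties toward lower
thresholds). With no significant pair it returns the surface with a null
selection and a warning rather than guessing.

## Distributional features

Acceleration magnitudes are binned into 30 × 1 m/s² bins over [0, 30),
angular velocity into 20 × 5 deg/s bins over [0, 100); bins are
half-open (numpy convention, last bin closed), out-of-range observations
are counted separately and excluded from normalization. The acceleration
ratio is count[1, 3) / count[0, 1) — time moving fast relative to time
barely moving; the angular-velocity ratio defaults to the analogous
high/low orientation count[5, 15) / count[0, 5), with the inverted
(low/high) reading available behind `literal=True` since the two
conventions are reciprocal and the field description is ambiguous.
Zero denominators yield an infinite sentinel which cohort statistics
exclude. Tilt moments (excess kurtosis g2, skewness g1, variance) use
population-moment definitions without small-sample bias correction —
with thousands of active samples per subject the correction is
immaterial, but the choice is recorded for exactness. The tilt
histogram uses 91 bins over [0°, 180°] (edges `linspace(0, 180, 92)`,
~1.98°/bin): the stated bin count is matched exactly rather than the
nominal 2° width.

## Sample Entropy

The Richman–Moorman estimator: templates x_i of lengths m and m+1 for
i = 0..N−m−1, pairwise Chebyshev distances, self-matches excluded,
SampEn = −ln(A/B). Undefined (NaN) when A or B is zero; a constant
series scores exactly 0. The kernel is vectorized (in-place max
accumulation over template components, O(N²(m+1)) work) and is verified
test-side against an independently written brute-force loop
implementation with exact equality on hundreds of random series.

Per-signal defaults: acceleration magnitude (m=2, r=0.25, N=250, 26 Hz),
angular-velocity magnitude (m=5, r=0.4, N=750, 52.6 Hz), tilt (m=3,
r=0.35, N=250, 52.6 Hz). Decisions where the procedure was
underdetermined:

* r is a multiple of the **per-window SD** (standard SampEn practice;
  makes the measure scale-invariant, verified to machine precision);
* down-sampling keeps every k-th sample with k = round(native/target),
  no anti-alias filter (an explicit choice: the aliasing behaviour is
  part of what makes reduced rates informative);
* each contiguous active segment is decimated, then split into
  non-overlapping N-sample windows, remainders discarded;
* undefined windows are excluded and the subject value is the arithmetic
  mean of the defined window entropies;
* the parameter grid search maximizes |Pearson r| between subject values
  and UEFM, skipping degenerate rows.

## Cohort statistics

Groups: severe UEFM < 30, moderate 30 ≤ UEFM < 50, mild ≥ 50 (cuts at
the emergence of hand function and of daily hand use). Per feature:
simple OLS regression vs UEFM (r, p, R² = r²), one-way ANOVA over the
three groups, and for the contrasts 1v2, 2v3, 1v23, 12v3 an unpaired
equal-variance t-test plus pooled-SD Cohen's D, signed as
(less-impaired mean − more-impaired mean)/s_pooled and reported as
magnitude in the table. VIF_i = 1/(1−R_i²) from regressing feature i on
the others with intercept; 1−R² < 1e−10 maps to an infinite sentinel;
VIF ≥ 5 is flagged. Backward elimination first drops features whose
simple correlation with UEFM has p ≥ 0.05 (two-sided), then removes the
highest-p coefficient one step at a time down to a single variable and
selects the minimum-AIC step; AIC = 2k − 2 ln L̂ with k counting slopes,
intercept and the residual variance (statsmodels' OLS AIC + 2 — a
constant offset that cannot change the ranking); ΔAIC < 2 marks models
with substantial empirical support. Repeated wearings per subject, when
present, are averaged to one feature vector by default (`mode="pool"`
treats them as independent observations).

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *statistical
structure* the pipeline is meant to detect, with known ground truth.
Per subject, a latent recovery draw r = UEFM + N(0, 4) drives four
parameters (small channel-specific noises on top), so the movement
phenotypes are correlated through one dimension, as in a real cohort:

* **active fraction** 0.18 + 0.22·(r/66) — inactive time falls from
  ~80% (severe) to ~60% (mild) of wear time;
* **tilt concentration** w = 0.15 + 0.70·σ((30−r)/5.5) — the weight of
  stagnant posture holds, falling steeply around the severe/moderate
  cut;
* **complexity level** c = 0.15 + 0.70·σ((r−50)/5.5) — the broadband
  share of within-bout tilt dynamics, rising steeply around the
  moderate/mild cut;
* **speed scale** (0.85 + 0.2·u)·lognormal(0.3) — a deliberately weak,
  noisy gradient in movement acceleration magnitudes.

Recordings alternate idle bouts (gravity + sensor noise) with ~40 s
movement bouts; idle lengths re-balance the running ratio so the
realized active fraction converges quickly. Within bouts, posture holds
of 4–9 s draw a base tilt from a scaled Beta on [0°, 180°] with mode 95°
— stagnant (concentration 300, SD ≈ 5°) with probability w, else
exploratory with a subject-specific spread σ_b ∝ (1−w)^−0.42: subjects
who leave the stagnant posture rarely leave it widely. This makes
pooled kurtosis strongly and variance only weakly impairment-dependent,
so peakedness and spread are semi-independent across subjects — a
single-concentration Beta would tie them deterministically. Within-bout
tilt dynamics are the convex mixture (1−c)·(0.5 Hz sinusoid) +
c·(slow AR(1), φ = 0.995), 12° RMS; the rougher part of tilt complexity
is carried by the *direction texture* of the movement bursts (a
near-periodic directional sweep at low c, broadband direction changes at
high c) riding perpendicular to gravity, which perturbs the
accelerometer-derived tilt without appearing in the gyroscope. Angular
rates are derived exactly from the orientation trajectory
(ω = v̇ × v + λv for the gravity direction v, with free spin λ about
gravity whose amount and regularity are subject-random), so the
generated gyro is kinematically consistent with the generated
accelerometer and the Madgwick filter behaves as it would on real data.
Movement bursts are slowly modulated, speed-scaled linear-acceleration
components with subject-random texture. All randomness flows from one
seeded generator per recording; identical profiles reproduce identical
recordings bit for bit.

What the generator does *not* emulate: whole-body posture changes
(lying/reclining), hand/finger movement, sensor dropout other than the
constant-signal pattern, non-uniform sampling, and real movement
kinematics beyond the bout/posture/texture structure. Passing the
end-to-end tests therefore shows that the pipeline recovers planted
statistical structure through a physically consistent sensor model — it
does not certify performance on real patient data.

### A structural caveat, recorded honestly

Two interactions cap how cleanly the planted effects can be recovered at
desk scale (30 subjects, 20 simulated minutes):

* With the SD-relative SampEn tolerance, windows containing posture
  transitions have inflated SD, which loosens the tolerance and
  compresses the tilt-complexity response exactly for posturally diverse
  subjects.
* Complexity "texture" conserves across channels: orientation-borne
  roughness appears in the gyroscope (the rates are kinematically
  coupled), and anything the gyroscope under-reports reappears as
  gravity-filter residual in the linear-acceleration channel. The
  entropy of the other channels therefore co-varies with tilt entropy to
  some degree, as it also does in the published cohort statistics of
  this field.

Consequently, across repeated synthetic cohorts the minimum-AIC model
almost always *retains* {tilt kurtosis, tilt SampEn} but often keeps one
additional co-varying feature — backward elimination keeps a spurious
extra variable with probability ≈ P(χ²₁ > 2) ≈ 0.16 per surviving
candidate even under ideal conditions. The acceptance experiment reports
both the exact-pair rate and the retained-pair rate.

## Problem sizes

Unit tests run on seconds-to-minutes of simulated signal. The end-to-end
recovery experiment uses 20 cohorts × 30 subjects × 20 simulated minutes
(52.6 Hz), chosen as the smallest scale at which the group contrasts and
model selection stabilize while a full run stays in the minutes range on
one CPU. The analysis scripts use one 22-subject cohort at the same
per-subject duration.
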