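# qome — quality of movement experience from a wrist IMU

After a stroke, people use their impaired arm less, and — the premise of
this package — in less *varied* and less *complex* ways. `qome` implements
an analysis pipeline that quantifies the statistical character of a day's
worth of arm movement ("quality of movement experience") from a wrist-worn
six-axis IMU, and relates those measures to the clinical impairment level
(Upper Extremity Fugl-Meyer score, UEFM, 0–66, higher = less impaired).
It is aimed at wearable-rehabilitation researchers who want movement
*diversity* and *complexity* targets, not just movement counts.

The pipeline:

1. **Gravity removal** — a Madgwick complementary orientation filter fuses
   accelerometer and gyroscope to subtract gravity from the acceleration.
2. **Inactivity filtering** — binary use score
   `u_t = 1{‖lin accel‖ > θ_u}` (θ_u = 0.1 G), trailing mean `U_t` over a
   D = 10 s window, keep samples with `U_t ≥ θ_U` (θ_U = 10%); constant
   sensor periods over 3 min are dropped as non-wear. Thresholds can be
   re-derived by a grid search over [0.05, 0.30]².
3. **Forearm tilt** — `Θ = arccos(−a_z/‖a‖)` on the raw (gravity-inclusive)
   acceleration, in [0°, 180°], restricted to active time.
4. **Features** — binned magnitude distributions (30 × 1 m/s² bins for
   acceleration, 20 × 5 deg/s bins for angular velocity), high/low
   magnitude ratios, magnitude means, and tilt-distribution moments
   (excess kurtosis = postural diversity, skewness, variance).
5. **Complexity** — Sample Entropy,
   `SampEn(m, r) = −ln(A/B)` with template-match counts `A` (length m+1)
   and `B` (length m) under Chebyshev distance ≤ r, on acceleration
   magnitude (m=2, r=0.25·SD, N=250, 26 Hz), angular-velocity magnitude
   (m=5, r=0.4·SD, N=750, 52.6 Hz) and tilt angle (m=3, r=0.35·SD, N=250,
   52.6 Hz), windowed within active segments.
6. **Cohort statistics** — per-feature regression vs UEFM, one-way ANOVA
   across severe (UEFM < 30) / moderate (30–49) / mild (≥ 50) groups,
   pooled-SD Cohen's D with t-tests for four contrasts, VIF = 1/(1−R²)
   multicollinearity checks, and minimum-AIC backward elimination
   (AIC = 2k − 2 ln L̂, ΔAIC < 2 = substantial support) of a multivariate
   UEFM model after prefiltering non-significant features.

Because raw patient recordings are not distributable, the package ships a
first-class synthetic cohort generator (`qome.synthetic`) that emulates
bout-structured wrist-IMU data whose latent impairment score drives the
activity fraction, postural concentration near a stagnant ~95° posture,
tilt complexity, and movement speed — so every stage of the pipeline can
be exercised and validated against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
22-subject synthetic cohort (20 simulated minutes each at 52.6 Hz):

```
$ python analysis/01_simulate_cohort.py
simulated 22 subjects, UEFM 10-65

$ python analysis/02_activity_filtering.py
inactive fraction vs UEFM: r=-0.72 (p=0.00014)
mean inactive time: severe 75% -> mild 60%
grid search over 36 threshold pairs; most lenient significant pair: theta_u=0.05 G, theta_U=0.05

$ python analysis/03_extract_features.py
features for 22 subjects -> results/features.csv
group 1: tilt-distribution peak 0.057 at 94 deg (8 subjects)
group 2: tilt-distribution peak 0.045 at 92 deg (8 subjects)
group 3: tilt-distribution peak 0.045 at 92 deg (6 subjects)

$ python analysis/04_cohort_statistics.py
strongest severe-vs-moderate separator: tilt_variance (|D|=1.62)
strongest moderate-vs-mild separator: sampen_tilt (|D|=3.66)
prefiltered out (not significant vs UEFM): ['tilt_skewness', 'accel_ratio', 'accel_mean', 'gyro_mean', 'sampen_accel', 'sampen_gyro']
minimum-AIC model: ['tilt_kurtosis', 'tilt_variance', 'gyro_ratio', 'sampen_tilt']
VIF of selected variables: {'tilt_kurtosis': 1.28, 'tilt_variance': 1.15, 'gyro_ratio': 1.28, 'sampen_tilt': 1.14}
```

Reading this: more-impaired subjects are inactive a larger share of wear
time (r = -0.72); the severe group's tilt distribution peaks sharply near
95 deg (postural stagnation); Sample Entropy of tilt is the strongest
moderate-vs-mild separator; and the minimum-AIC model of UEFM is built on
postural diversity and complexity measures with low collinearity
(VIF close to 1). In this particular cohort draw the tilt variance edges
out kurtosis for the severe-vs-moderate contrast and two extra variables
survive the elimination — any single 22-subject cohort is one random
draw; the distribution of these outcomes across many cohorts is what
`scripts/acceptance.py` measures.

A `qome` console command exposes the same stages for single files
(`qome simulate | preprocess | features | sampen | cohort`); see
`qome --help`.

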