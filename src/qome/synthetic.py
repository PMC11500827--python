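"""Synthetic wrist-IMU cohort generator.

The study conditions this generator emulates: chronic stroke survivors wear a
wrist IMU (triaxial accelerometer in m/s^2, triaxial gyroscope in deg/s,
sampled at 52.6 Hz) for part of a day.  A latent impairment score (UEFM,
0-66, higher = less impaired) controls four gradients that the downstream
pipeline is supposed to recover:

* the fraction of wear time spent in movement bouts rises with UEFM
  (inactive time falls from roughly 80% to 60% across the score range);
* the forearm tilt-angle distribution is concentrated near a stagnant
  posture around 95 deg for severe impairment and broadens with recovery;
* the tilt trajectory within movement bouts becomes more complex (broadband
  vs a single slow oscillation) with recovery;
* movement acceleration magnitudes scale up with recovery.

Every recording is generated from a single seeded ``numpy.random.Generator``
so that identical profiles reproduce identical recordings bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt
from scipy.ndimage import uniform_filter1d

GRAVITY = 9.81
DEFAULT_FS = 52.6
TILT_MODE_DEG = 95.0

# concentrations of the scaled-Beta posture law (mode 95 deg)
_KAPPA_STAGNANT = 300.0    # SD ~ 5 deg: the stagnant resting posture
_KAPPA_IDLE = 150.0
_KAPPA_EXPLORE_MEAN = 6.0  # SD ~ 30 deg: exploratory postures

_ACTIVE_BOUT_MEAN_S = 40.0       # matches observed segmentation cadence
_POSTURE_EPISODE_S = (4.0, 9.0)  # sub-bout posture-hold duration range, s
_TILT_DYNAMICS_AMPLITUDE = 12.0  # deg, RMS scale of within-bout tilt motion
_LIN_ACCEL_SD = 0.9              # m/s^2 per axis before speed scaling
_YAW_RATE_SD = 1.0               # rad/s, spin about gravity during bouts


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject parameters driving one synthetic recording.

    tilt_concentration is the weight, in (0, 1), of movement bouts anchored
    at the stagnant ~95 deg posture; higher values give a narrower pooled
    tilt distribution.  complexity_level mixes a 0.5 Hz oscillation
    (weight 1-c) with a broadband autoregressive process (weight c) in the
    within-bout tilt dynamics.  speed_scale multiplies movement
    acceleration magnitudes.
    """

    subject_id: str
    uefm: int
    active_fraction: float
    tilt_concentration: float
    complexity_level: float
    speed_scale: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.uefm <= 66:
            raise ValueError(f"uefm must be in [0, 66], got {self.uefm}")
        if not 0.0 <= self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in [0, 1)")
        if not 0.0 < self.tilt_concentration < 1.0:
            raise ValueError("tilt_concentration must be in (0, 1)")
        if not 0.0 <= self.complexity_level <= 1.0:
            raise ValueError("complexity_level must be in [0, 1]")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be positive")


@dataclass
class RecordingTruth:
    """Generative ground truth stored alongside a synthetic recording."""

    tilt_deg: np.ndarray          # latent tilt trajectory, deg
    active_mask: np.ndarray       # True where the schedule put a movement bout
    lin_accel: np.ndarray         # injected linear acceleration, (n, 3) m/s^2


@dataclass
class IMURecording:
    """Raw per-subject sensor time series.

    accel is gravity-inclusive in the sensor frame: a static device with its
    z axis up reads (0, 0, -9.81) m/s^2, so the tilt angle is
    arccos(-a_z/||a||).  gyro is in deg/s.
    """

    subject_id: str
    sampling_rate_hz: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    truth: RecordingTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("t, accel and gyro must have matching lengths")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate_hz, rtol=1e-6):
                raise ValueError("timestamps must be uniform at 1/fs spacing")
        for arr in (self.t, self.accel, self.gyro):
            if not np.all(np.isfinite(arr)):
                raise ValueError("recording contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)


def _scaled_beta(rng: np.random.Generator, concentration: float,
                 size=None, mode_deg: float = TILT_MODE_DEG) -> np.ndarray:
    """Draw tilt angles from a Beta on [0, 180] deg with the given mode."""
    m = mode_deg / 180.0
    a = 1.0 + concentration * m
    b = 1.0 + concentration * (1.0 - m)
    return 180.0 * rng.beta(a, b, size)


def _smooth_ar(rng: np.random.Generator, n: int, phi: float,
               order: int = 2) -> np.ndarray:
    """Unit-SD smooth stochastic process: cascaded AR(1) stages."""
    burn = 200
    x = rng.standard_normal(n + burn)
    for _ in range(order):
        x = lfilter([1.0], [1.0, -phi], x)
    x = x[burn:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _bout_schedule(rng: np.random.Generator, n: int, fs: float,
                   active_fraction: float) -> np.ndarray:
    """Alternating idle/active schedule whose realized active fraction
    tracks the target (idle lengths are chosen to re-balance the running
    ratio, so the fraction converges quickly with duration)."""
    active = np.zeros(n, dtype=bool)
    if active_fraction <= 0:
        return active
    i = int(rng.uniform(5.0, 15.0) * fs)   # idle lead-in
    cum_active = 0.0
    while i < n:
        act_s = rng.uniform(0.5, 1.5) * _ACTIVE_BOUT_MEAN_S
        act_n = max(1, int(round(act_s * fs)))
        j = min(n, i + act_n)
        active[i:j] = True
        cum_active += (j - i) / fs
        cum_idle = (j - cum_active * fs) / fs
        target_idle = cum_active * (1.0 - active_fraction) / active_fraction
        idle_s = max(3.0, target_idle - cum_idle)
        i = j + int(round(idle_s * fs))
    return active


def _bout_slices(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index pairs of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _episode_envelope(rng: np.random.Generator, n: int, fs: float,
                      duty: float = 1.0) -> np.ndarray:
    """Movement-episode duty cycle inside an active bout: a few seconds of
    motion, brief pauses, smoothed to be continuous.  ``duty`` rescales the
    on/off balance (subject-specific movement style)."""
    env = np.zeros(n)
    i = 0
    on = True
    while i < n:
        dur = duty * (rng.uniform(1.5, 4.0) if on
                      else rng.uniform(0.5, 2.0) / duty ** 2)
        j = min(n, i + max(1, int(round(dur * fs))))
        if on:
            env[i:j] = 1.0
        i = j
        on = not on
    return uniform_filter1d(env, max(1, int(round(0.3 * fs))))


def generate_recording(profile: SubjectProfile, duration_s: float,
                       fs: float = DEFAULT_FS,
                       accel_noise_sd: float = 0.05,
                       gyro_noise_sd: float = 3.0,
                       tilt_dynamics_amplitude: float = _TILT_DYNAMICS_AMPLITUDE,
                       lin_accel_sd: float = _LIN_ACCEL_SD,
                       ) -> IMURecording:
    """Simulate one wrist-IMU recording from a subject profile.

    The recording alternates idle bouts (gravity + sensor noise only) and
    active bouts.  Ground truth (latent tilt, bout mask, injected linear
    acceleration) is attached as ``recording.truth``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(profile.seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    active = _bout_schedule(rng, n, fs, profile.active_fraction)

    # --- latent tilt trajectory -------------------------------------------
    # Posture holds of a few seconds within each movement bout: stagnant
    # (high concentration near 95 deg) with probability tilt_concentration,
    # else exploratory (broad, subject-specific concentration).  Smoothed
    # so transitions are physical.
    # Exploratory-posture spread: wider when excursions are rarer (severe
    # subjects leave the stagnant posture seldom but widely), so the pooled
    # variance varies far less across impairment than the pooled kurtosis,
    # which remains driven by the stagnant weight.
    w = profile.tilt_concentration
    sigma_b = ((18.0 + 8.0 * profile.speed_scale)
               * float(np.exp(rng.normal(0.0, 0.3)))
               / (1.0 - w) ** 0.42)
    kappa_explore = max(0.8, (90.0 / sigma_b) ** 2 - 3.0)
    explore_mode = float(np.clip(TILT_MODE_DEG + rng.normal(0.0, 10.0),
                                 35.0, 150.0))
    base = np.empty(n)
    bouts = _bout_slices(active)
    idle_bouts = _bout_slices(~active)
    for (i, j) in idle_bouts:
        base[i:j] = _scaled_beta(rng, _KAPPA_IDLE)
    for (i, j) in bouts:
        k = i
        while k < j:
            hold = int(round(rng.uniform(*_POSTURE_EPISODE_S) * fs))
            stagnant = rng.uniform() < profile.tilt_concentration
            kappa = _KAPPA_STAGNANT if stagnant else kappa_explore
            mode = TILT_MODE_DEG if stagnant else explore_mode
            base[k:min(j, k + hold)] = _scaled_beta(rng, kappa, mode_deg=mode)
            k += hold
    base = uniform_filter1d(base, max(1, int(round(1.5 * fs))))

    # Within-bout dynamics: convex mixture of a 0.5 Hz oscillation and a
    # broadband smooth AR process, unit RMS each.
    c = profile.complexity_level
    phase = rng.uniform(0, 2 * np.pi)
    osc = np.sqrt(2.0) * np.sin(2 * np.pi * 0.5 * t + phase)
    broad = _smooth_ar(rng, n, phi=0.995, order=1)
    dyn = tilt_dynamics_amplitude * ((1.0 - c) * osc + c * broad)
    tilt = np.clip(base + np.where(active, dyn, 0.0), 1.0, 179.0)

    # Azimuth of the tilt direction, per bout, smoothed.
    psi = np.empty(n)
    for (i, j) in idle_bouts + bouts:
        psi[i:j] = rng.uniform(0, 2 * np.pi)
    psi = uniform_filter1d(psi, max(1, int(round(1.0 * fs))))

    # Gravity field direction in the sensor frame (unit vector).
    th = np.radians(tilt)
    ghat = np.column_stack([np.sin(th) * np.cos(psi),
                            np.sin(th) * np.sin(psi),
                            -np.cos(th)])

    # --- exact body rates from the orientation trajectory ------------------
    # For a world-fixed vector v expressed in the rotating sensor frame,
    # dv/dt = v x omega, solved by omega = (dv/dt) x v + lambda v, where
    # lambda is free spin about gravity (yaw).
    dghat = np.gradient(ghat, dt, axis=0)
    omega = np.cross(dghat, ghat)             # rad/s, minimal rotation
    # wrist-spin style varies by subject: amount and regularity of the
    # spin about gravity are subject-random, independent of impairment
    yaw_sd = 1.2 * _YAW_RATE_SD * float(np.exp(rng.normal(0.0, 0.45)))
    eta_yaw = rng.uniform(0.15, 0.85)
    yaw_osc = np.sqrt(2.0) * np.sin(2 * np.pi * 0.8 * t + rng.uniform(0, 2 * np.pi))
    yaw_rate = yaw_sd * ((1.0 - eta_yaw) * yaw_osc
                         + eta_yaw * _smooth_ar(rng, n, phi=0.8, order=1))
    omega += (yaw_rate * active)[:, None] * ghat
    gyro = np.degrees(omega)
    # gyro sensor bandwidth: rates reported through a ~5 Hz low-pass
    sos = butter(2, 5.0, btype="low", fs=fs, output="sos")
    gyro = sosfiltfilt(sos, gyro, axis=0)

    # --- linear acceleration bursts ---------------------------------------
    # Movement bursts: slowly modulated, speed-scaled linear acceleration
    # with subject-specific texture (burst smoothness and duty cycle vary
    # by person, independent of impairment).
    lin = np.zeros((n, 3))
    phi_lin = rng.uniform(0.985, 0.995)
    duty = float(np.exp(rng.normal(0.0, 0.06)))
    f_sweep = rng.uniform(0.5, 0.9)
    for (i, j) in bouts:
        m = j - i
        env = _episode_envelope(rng, m, fs, duty=duty)
        for ax in range(3):
            lin[i:j, ax] = (profile.speed_scale * lin_accel_sd
                            * env * _smooth_ar(rng, m, phi=phi_lin, order=1))
        # movement-direction texture: while moving, part of the burst swings
        # perpendicular to gravity with the complexity mixture's texture -
        # a periodic sweep at low complexity, broadband at high complexity.
        # It scales with the instantaneous burst magnitude, so it shifts the
        # accelerometer *direction* (hence measured tilt) without adding
        # texture to the burst magnitude itself.
        g0 = ghat[i:j].mean(axis=0)
        g0 /= np.linalg.norm(g0)
        ref = (np.array([0.0, 0.0, 1.0]) if abs(g0[2]) < 0.9
               else np.array([1.0, 0.0, 0.0]))
        e_perp = np.cross(g0, ref)
        e_perp /= np.linalg.norm(e_perp)
        tex = ((1.0 - c) * np.sqrt(2.0) * np.sin(2 * np.pi * f_sweep * t[i:j]
                                                 + rng.uniform(0, 2 * np.pi))
               + c * _smooth_ar(rng, m, phi=0.85, order=1))
        rad_mag = np.linalg.norm(lin[i:j], axis=1)
        lin[i:j] += (0.5 * rad_mag * tex)[:, None] * e_perp

    accel = GRAVITY * ghat + lin
    accel = accel + rng.normal(0.0, accel_noise_sd, (n, 3))
    gyro = gyro + rng.normal(0.0, gyro_noise_sd, (n, 3))

    truth = RecordingTruth(tilt_deg=tilt, active_mask=active, lin_accel=lin)
    return IMURecording(subject_id=profile.subject_id, sampling_rate_hz=fs,
                        t=t, accel=accel, gyro=gyro, truth=truth)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def profile_from_uefm(subject_id: str, uefm: int,
                      rng: np.random.Generator) -> SubjectProfile:
    """Map a UEFM score to latent generator parameters.

    The two injected effects sit at the clinical group cuts: the stagnant-
    posture weight falls steeply around UEFM 30 and the tilt-complexity
    level rises steeply around UEFM 50; activity and speed follow weaker,
    noisier linear gradients.
    """
    # One latent recovery dimension drives every gradient (plus small
    # channel-specific noise), the way a single construct underlies the
    # correlated movement phenotypes of a real cohort.
    r = float(np.clip(uefm + rng.normal(0.0, 4.0), 0.0, 66.0))
    u = r / 66.0
    active = float(np.clip(0.18 + 0.22 * u + rng.normal(0, 0.02), 0.05, 0.7))
    conc = float(np.clip(0.15 + 0.70 * _sigmoid((30.0 - r) / 5.5)
                         + rng.normal(0, 0.02), 0.05, 0.95))
    comp = float(np.clip(0.15 + 0.70 * _sigmoid((r - 50.0) / 5.5)
                         + rng.normal(0, 0.02), 0.0, 1.0))
    speed = float(np.clip((0.85 + 0.2 * u) * np.exp(rng.normal(0, 0.3)),
                          0.55, 2.0))
    seed = int(rng.integers(0, 2**31 - 1))
    return SubjectProfile(subject_id=subject_id, uefm=int(uefm),
                          active_fraction=active, tilt_concentration=conc,
                          complexity_level=comp, speed_scale=speed, seed=seed)


def synthesize_bbt(uefm: int, rng: np.random.Generator) -> int:
    """Box-and-Blocks count consistent with hand function emerging ~UEFM 30."""
    if uefm < 30:
        return int(np.clip(rng.integers(0, 3), 0, 2))
    return int(np.clip(round(1.4 * (uefm - 28) + rng.normal(0, 4)), 0, 70))


def generate_cohort(n: int, uefm_range: tuple[int, int] = (10, 65),
                    seed: int = 0, duration_s: float = 1200.0,
                    fs: float = DEFAULT_FS,
                    **recording_kwargs,
                    ) -> list[tuple[SubjectProfile, IMURecording]]:
    """Generate a synthetic cohort with known impairment gradients.

    UEFM scores are spread evenly over ``uefm_range`` so all impairment
    groups are populated; latent parameters are monotone in UEFM with
    additive subject noise (see :func:`profile_from_uefm`).
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    lo, hi = uefm_range
    if not (0 <= lo < hi <= 66):
        raise ValueError("uefm_range must satisfy 0 <= lo < hi <= 66")
    rng = np.random.default_rng(seed)
    uefms = np.round(np.linspace(lo, hi, n)).astype(int)
    cohort = []
    for k, uefm in enumerate(uefms):
        profile = profile_from_uefm(f"S{k:03d}", int(uefm), rng)
        rec = generate_recording(profile, duration_s, fs=fs,
                                 **recording_kwargs)
        cohort.append((profile, rec))
    return cohort


# --- plain-text I/O ---------------------------------------------------------

RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def write_recording_csv(rec: IMURecording, path: str | Path) -> None:
    df = pd.DataFrame(np.column_stack([rec.t, rec.accel, rec.gyro]),
                      columns=RECORDING_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path: str | Path, subject_id: str | None = None,
                       sampling_rate_hz: float | None = None) -> IMURecording:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    # timestamps are stored at limited precision; rebuild the uniform grid
    t = t[0] + np.arange(len(t)) / sampling_rate_hz
    return IMURecording(subject_id=subject_id or Path(path).stem,
                        sampling_rate_hz=sampling_rate_hz, t=t,
                        accel=df[["ax", "ay", "az"]].to_numpy(),
                        gyro=df[["gx", "gy", "gz"]].to_numpy())


def write_cohort(cohort, out_dir: str | Path, seed: int | None = None) -> None:
    """Write per-subject recording CSVs, a metadata CSV and a ground-truth
    JSON (latent profile parameters; the full tilt trajectories stay with
    the in-memory recordings)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows, truth = [], {}
    rng = np.random.default_rng(0 if seed is None else seed)
    for profile, rec in cohort:
        write_recording_csv(rec, out / f"{profile.subject_id}.csv")
        meta_rows.append({"subject_id": profile.subject_id,
                          "uefm": profile.uefm,
                          "bbt": synthesize_bbt(profile.uefm, rng)})
        truth[profile.subject_id] = {
            "uefm": profile.uefm,
            "active_fraction": profile.active_fraction,
            "tilt_concentration": profile.tilt_concentration,
            "complexity_level": profile.complexity_level,
            "speed_scale": profile.speed_scale,
            "seed": profile.seed,
        }
    pd.DataFrame(meta_rows).to_csv(out / "cohort.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
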