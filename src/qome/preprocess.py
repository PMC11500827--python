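"""Gravity removal and arm-inactivity filtering.

The activity filter follows the two-threshold scheme used in wrist-worn
arm-use studies: an instantaneous binary use score

    u_t = 1  if ||linear acceleration at t|| > theta_u   (theta_u in G)

and its trailing mean over a D-second sliding window,

    U_t = (1/D) * integral_{t-D}^{t} u dx,

with samples kept (arm "active") where U_t >= theta_U.  Defaults are
theta_u = 0.1 G, theta_U = 10%, D = 10 s; periods where all six sensor
channels stay constant for over three minutes are treated as non-wear and
dropped first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GRAVITY, IMURecording

try:  # jitted Madgwick kernel; the pure-Python fallback is ~100x slower
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True)(fn)
except ImportError:  # pragma: no cover
    def _jit(fn):
        return fn


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the inactivity filter (theta_u in G units)."""

    theta_u: float = 0.1
    theta_U: float = 0.10
    window_D_s: float = 10.0
    dropout_min_s: float = 180.0
    constant_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_u <= 0:
            raise ValueError("theta_u must be positive")
        if not 0.0 <= self.theta_U < 1.0:
            raise ValueError("theta_U must be in [0, 1)")
        if self.window_D_s <= 0:
            raise ValueError("window_D_s must be positive")
        if self.dropout_min_s <= 0:
            raise ValueError("dropout_min_s must be positive")


@dataclass
class ActivityAnnotation:
    """Per-sample activity decision plus derived bookkeeping."""

    u: np.ndarray                 # binary use score
    U: np.ndarray                 # trailing windowed mean of u
    keep_mask: np.ndarray         # True where the arm counts as active
    segments: list[tuple[int, int]]   # half-open maximal kept runs
    total_active_s: float
    total_inactive_s: float
    inactive_fraction: float


# --- Madgwick-style gravity removal ----------------------------------------

def _madgwick_core(acc, gyr_rad, dt, beta, q0):
    """Sequential IMU-only Madgwick update; returns quaternion per sample.

    acc must be the *negated* raw acceleration (so a static sensor reads
    +g along the world-up reference used by the textbook formulation).
    """
    n = acc.shape[0]
    q = np.empty((n, 4))
    q0w, q0x, q0y, q0z = q0[0], q0[1], q0[2], q0[3]
    for i in range(n):
        gx, gy, gz = gyr_rad[i, 0], gyr_rad[i, 1], gyr_rad[i, 2]
        # rate of change from gyroscope
        qdw = 0.5 * (-q0x * gx - q0y * gy - q0z * gz)
        qdx = 0.5 * (q0w * gx + q0y * gz - q0z * gy)
        qdy = 0.5 * (q0w * gy - q0x * gz + q0z * gx)
        qdz = 0.5 * (q0w * gz + q0x * gy - q0y * gx)

        ax, ay, az = acc[i, 0], acc[i, 1], acc[i, 2]
        norm = (ax * ax + ay * ay + az * az) ** 0.5
        if norm > 1e-12:
            ax, ay, az = ax / norm, ay / norm, az / norm
            # gradient-descent corrective step
            f1 = 2.0 * (q0x * q0z - q0w * q0y) - ax
            f2 = 2.0 * (q0w * q0x + q0y * q0z) - ay
            f3 = 2.0 * (0.5 - q0x * q0x - q0y * q0y) - az
            s0 = -2.0 * q0y * f1 + 2.0 * q0x * f2
            s1 = 2.0 * q0z * f1 + 2.0 * q0w * f2 - 4.0 * q0x * f3
            s2 = -2.0 * q0w * f1 + 2.0 * q0z * f2 - 4.0 * q0y * f3
            s3 = 2.0 * q0x * f1 + 2.0 * q0y * f2
            snorm = (s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3) ** 0.5
            if snorm > 1e-12:
                qdw -= beta * s0 / snorm
                qdx -= beta * s1 / snorm
                qdy -= beta * s2 / snorm
                qdz -= beta * s3 / snorm

        q0w += qdw * dt
        q0x += qdx * dt
        q0y += qdy * dt
        q0z += qdz * dt
        qn = (q0w * q0w + q0x * q0x + q0y * q0y + q0z * q0z) ** 0.5
        q0w, q0x, q0y, q0z = q0w / qn, q0x / qn, q0y / qn, q0z / qn
        q[i, 0], q[i, 1], q[i, 2], q[i, 3] = q0w, q0x, q0y, q0z
    return q


_madgwick_jit = _jit(_madgwick_core)


def _init_quaternion(a_up: np.ndarray) -> np.ndarray:
    """Body-to-world quaternion whose sensor-frame up equals a_up.

    Shortest-arc rotation taking a_up onto world-up (0,0,1), so that the
    filter starts aligned with the first accelerometer sample.
    """
    v = a_up / np.linalg.norm(a_up)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 deg about x
    axis = np.cross(v, z)
    q = np.array([1.0 + c, axis[0], axis[1], axis[2]])
    return q / np.linalg.norm(q)


def madgwick_gravity(rec: IMURecording, beta: float = 0.1) -> np.ndarray:
    """Per-sample gravity vector estimate in the sensor frame (m/s^2)."""
    fs = rec.sampling_rate_hz
    min_n = int(round(5.0 * fs))
    if len(rec) < min_n:
        raise ValueError(
            f"recording too short for filter convergence ({len(rec)} < {min_n})")
    acc_std = -rec.accel  # convert to world-up convention
    q0 = _init_quaternion(acc_std[0])
    q = _madgwick_jit(np.ascontiguousarray(acc_std),
                      np.ascontiguousarray(np.radians(rec.gyro)),
                      1.0 / fs, beta, q0)
    qw, qx, qy, qz = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # world-up expressed in the sensor frame
    up = np.column_stack([2.0 * (qx * qz - qw * qy),
                          2.0 * (qw * qx + qy * qz),
                          qw * qw - qx * qx - qy * qy + qz * qz])
    return -GRAVITY * up  # gravity field points down


def remove_gravity(rec: IMURecording, beta: float = 0.1) -> np.ndarray:
    """Linear acceleration: raw accel minus the Madgwick gravity estimate."""
    return rec.accel - madgwick_gravity(rec, beta=beta)


# --- dropout (non-wear) removal --------------------------------------------

def drop_constant_periods(rec: IMURecording, dropout_min_s: float = 180.0,
                          tol: float = 0.0) -> np.ndarray:
    """Keep mask that drops maximal runs where all six channels are constant
    (within ``tol`` per channel) for longer than ``dropout_min_s``."""
    if dropout_min_s <= 0:
        raise ValueError("dropout_min_s must be positive")
    sig = np.column_stack([rec.accel, rec.gyro])
    n = len(rec)
    keep = np.ones(n, dtype=bool)
    if n < 2:
        return keep
    changed = np.any(np.abs(np.diff(sig, axis=0)) > tol, axis=1)
    # boundaries of maximal constant runs: indices where the signal changes
    run_start = 0
    min_n = dropout_min_s * rec.sampling_rate_hz
    for i in range(n - 1):
        if changed[i]:
            if (i + 1 - run_start) > min_n:
                keep[run_start:i + 1] = False
            run_start = i + 1
    if (n - run_start) > min_n:
        keep[run_start:n] = False
    return keep


# --- two-threshold activity filter -----------------------------------------

def _trailing_mean(u: np.ndarray, window: int) -> np.ndarray:
    """Mean of u over the trailing ``window`` samples (partial at the start)."""
    cs = np.concatenate([[0.0], np.cumsum(u)])
    idx = np.arange(1, len(u) + 1)
    lo = np.maximum(0, idx - window)
    return (cs[idx] - cs[lo]) / (idx - lo)


def _kept_segments(keep: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], keep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def activity_filter(lin_accel: np.ndarray, cfg: FilterConfig, fs: float,
                    wear_mask: np.ndarray | None = None) -> ActivityAnnotation:
    """Apply the two-threshold inactivity filter to linear acceleration.

    ``lin_accel`` may be an (n, 3) vector series or an (n,) magnitude
    series.  Samples outside ``wear_mask`` (dropout periods) count neither
    as active nor toward wear time.
    """
    lin_accel = np.asarray(lin_accel, dtype=float)
    mag = (np.linalg.norm(lin_accel, axis=1)
           if lin_accel.ndim == 2 else lin_accel)
    n = len(mag)
    window = max(1, int(round(cfg.window_D_s * fs)))
    if window > n:
        raise ValueError("window longer than recording")
    u = (mag > cfg.theta_u * GRAVITY).astype(float)
    if wear_mask is not None:
        u = np.where(wear_mask, u, 0.0)
    U = _trailing_mean(u, window)
    keep = U >= cfg.theta_U
    if wear_mask is not None:
        keep &= wear_mask
        wear_n = int(wear_mask.sum())
    else:
        wear_n = n
    segments = _kept_segments(keep)
    active_s = float(keep.sum()) / fs
    wear_s = wear_n / fs
    inactive_s = wear_s - active_s
    frac = inactive_s / wear_s if wear_s > 0 else float("nan")
    return ActivityAnnotation(u=u, U=U, keep_mask=keep, segments=segments,
                              total_active_s=active_s,
                              total_inactive_s=inactive_s,
                              inactive_fraction=frac)


def annotate_recording(rec: IMURecording, cfg: FilterConfig = FilterConfig(),
                       beta: float = 0.1):
    """Gravity removal + dropout removal + activity filter for one recording.

    Returns (linear acceleration, ActivityAnnotation).
    """
    lin = remove_gravity(rec, beta=beta)
    wear = drop_constant_periods(rec, cfg.dropout_min_s, tol=cfg.constant_tol)
    ann = activity_filter(lin, cfg, rec.sampling_rate_hz, wear_mask=wear)
    return lin, ann


# --- threshold grid search --------------------------------------------------

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.3001, 0.05), 2))


@dataclass
class GridSearchResult:
    table: pd.DataFrame            # one row per (theta_u, theta_U) pair
    selected: tuple[float, float] | None
    alpha: float = 0.05

    @property
    def surface(self) -> pd.DataFrame:
        return self.table.pivot(index="theta_u", columns="theta_U",
                                values="pearson_r")


def grid_search_thresholds(lin_mags: list[np.ndarray], uefm: np.ndarray,
                           fs: float,
                           theta_u_grid=DEFAULT_THRESHOLD_GRID,
                           theta_U_grid=DEFAULT_THRESHOLD_GRID,
                           window_D_s: float = 10.0,
                           alpha: float = 0.05) -> GridSearchResult:
    """Choose the most lenient threshold pair whose inactive-fraction /
    UEFM Pearson correlation is significant.

    Among pairs with two-sided p < alpha, the pair retaining the most data
    (largest mean active fraction) is selected; ties break toward lower
    thresholds.  If no pair is significant, ``selected`` is None and a
    warning is raised.
    """
    uefm = np.asarray(uefm, dtype=float)
    if len(lin_mags) < 3:
        raise ValueError("grid search needs at least 3 subjects")
    window = max(1, int(round(window_D_s * fs)))
    rows = []
    for tu in theta_u_grid:
        Us = [_trailing_mean((m > tu * GRAVITY).astype(float), window)
              for m in lin_mags]
        for tU in theta_U_grid:
            active = np.array([float(np.mean(U >= tU)) for U in Us])
            inactive = 1.0 - active
            if np.std(inactive) == 0 or np.std(uefm) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(inactive, uefm)
            rows.append({"theta_u": float(tu), "theta_U": float(tU),
                         "pearson_r": r, "p_value": p,
                         "mean_active_fraction": float(active.mean()),
                         "significant": bool(np.isfinite(p) and p < alpha)})
    table = pd.DataFrame(rows)
    sig = table[table["significant"]]
    if sig.empty:
        warnings.warn("no threshold pair reached a significant "
                      "inactive-fraction/UEFM correlation")
        return GridSearchResult(table=table, selected=None, alpha=alpha)
    best = sig.sort_values(["mean_active_fraction", "theta_u", "theta_U"],
                           ascending=[False, True, True]).iloc[0]
    return GridSearchResult(table=table,
                            selected=(best["theta_u"], best["theta_U"]),
                            alpha=alpha)
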