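"""Distributional quality-of-movement-experience features.

Binned magnitude distributions (30 x 1 m/s^2 bins for acceleration,
20 x 5 deg/s bins for angular velocity), high/low magnitude ratios,
magnitude means, tilt-distribution moments (excess kurtosis, skewness,
variance) and the 91-bin tilt-angle histogram over [0, 180] deg.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .orientation import TiltSeries

ACCEL_EDGES = np.arange(0.0, 31.0, 1.0)     # m/s^2
GYRO_EDGES = np.arange(0.0, 101.0, 5.0)     # deg/s
TILT_EDGES = np.linspace(0.0, 180.0, 92)    # 91 bins, ~1.978 deg each

#: Table of cohort features, in presentation order.
FEATURE_NAMES = [
    "tilt_kurtosis", "tilt_skewness", "tilt_variance",
    "accel_ratio", "gyro_ratio",
    "accel_mean", "gyro_mean",
    "sampen_accel", "sampen_gyro", "sampen_tilt",
]


@dataclass
class MagnitudeHistogram:
    kind: str                 # "accel" | "gyro" | "tilt"
    edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray    # proportions over in-range observations
    n_out_of_range: int


@dataclass
class QOMEFeatureVector:
    """One recording's movement-experience quality features."""

    tilt_kurtosis: float
    tilt_skewness: float
    tilt_variance: float
    accel_ratio: float
    gyro_ratio: float
    accel_mean: float
    gyro_mean: float
    sampen_accel: float
    sampen_gyro: float
    sampen_tilt: float
    inactive_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def _histogram(mags: np.ndarray, edges: np.ndarray, kind: str
               ) -> MagnitudeHistogram:
    mags = np.asarray(mags, dtype=float)
    if mags.size == 0:
        raise ValueError("empty magnitude series")
    counts, _ = np.histogram(mags, bins=edges)
    in_range = int(counts.sum())
    out = int(mags.size - in_range)
    norm = counts / in_range if in_range > 0 else np.zeros_like(counts, float)
    return MagnitudeHistogram(kind=kind, edges=edges, counts=counts,
                              normalized=norm, n_out_of_range=out)


def magnitude_histogram(mags: np.ndarray, kind: str) -> MagnitudeHistogram:
    """Binned magnitude distribution over active time.

    Bins are half-open [lo, hi) (numpy convention; last bin closed);
    out-of-range observations are counted separately and excluded from the
    normalization.
    """
    if kind == "accel":
        return _histogram(mags, ACCEL_EDGES, "accel")
    if kind == "gyro":
        return _histogram(mags, GYRO_EDGES, "gyro")
    raise ValueError(f"unknown histogram kind {kind!r}")


def accel_ratio(hist: MagnitudeHistogram) -> float:
    """Observations in [1, 3) m/s^2 over observations in [0, 1) m/s^2.

    Higher values mean relatively more time at higher accelerations.
    Returns +inf when nothing falls below 1 m/s^2 (flagged downstream).
    """
    num = float(hist.counts[1:3].sum())
    den = float(hist.counts[0])
    return num / den if den > 0 else float("inf")


def gyro_ratio(hist: MagnitudeHistogram, literal: bool = False) -> float:
    """Angular-velocity analogue: observations in [5, 15) deg/s over
    observations in [0, 5) deg/s.

    ``literal=True`` flips the ratio to the low/high orientation.
    """
    high = float(hist.counts[1:3].sum())
    low = float(hist.counts[0])
    num, den = (low, high) if literal else (high, low)
    return num / den if den > 0 else float("inf")


def tilt_moments(tilt: TiltSeries) -> tuple[float, float, float]:
    """(excess kurtosis, skewness, variance in deg^2) of valid tilt samples.

    Population-moment definitions (no small-sample bias correction);
    a constant series has undefined kurtosis and raises.
    """
    vals = tilt.values
    if vals.size < 4:
        raise ValueError("tilt moments need at least 4 valid samples")
    var = float(np.var(vals))
    if var == 0:
        raise ValueError("tilt distribution is degenerate (zero variance)")
    kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    skew = float(stats.skew(vals, bias=True))
    return kurt, skew, var


def magnitude_means(accel_mags: np.ndarray, gyro_mags: np.ndarray
                    ) -> tuple[float, float]:
    """Arithmetic means of the active-masked magnitude series."""
    accel_mags = np.asarray(accel_mags, float)
    gyro_mags = np.asarray(gyro_mags, float)
    if accel_mags.size == 0 or gyro_mags.size == 0:
        raise ValueError("empty magnitude series")
    return float(accel_mags.mean()), float(gyro_mags.mean())


def tilt_histogram(tilt: TiltSeries) -> MagnitudeHistogram:
    """Normalized 91-bin tilt-angle distribution over [0, 180] deg."""
    vals = tilt.values
    if vals.size == 0:
        raise ValueError("no valid tilt samples")
    return _histogram(vals, TILT_EDGES, "tilt")
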