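"""Forearm tilt angle with respect to gravity.

Applied to the *raw* (gravity-inclusive) acceleration: with gravity
dominating the measurement, the angle between the device's -z axis and the
world vertical is

    Theta = arccos( -a_z / sqrt(a_x^2 + a_y^2 + a_z^2) )   in [0, 180] deg.

Sensor frame: when the hand is pronated and the forearm horizontal, +X is
posterior, +Y medial, +Z vertical, so a static device reads (0, 0, -g) at
Theta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .preprocess import ActivityAnnotation
from .synthetic import IMURecording


@dataclass
class TiltSeries:
    theta: np.ndarray   # deg, in [0, 180] where valid
    mask: np.ndarray    # per-sample validity (and, downstream, activity)

    @property
    def values(self) -> np.ndarray:
        """Tilt angles at valid samples only."""
        return self.theta[self.mask]


def tilt_angle(accel: np.ndarray, magnitude_floor: float = 0.5,
               smooth_s: float | None = None,
               fs: float | None = None) -> TiltSeries:
    """Tilt-angle series from raw acceleration vectors.

    Samples whose magnitude is below ``magnitude_floor`` (m/s^2) are
    flagged invalid rather than raising.  An optional boxcar smoother of
    ``smooth_s`` seconds can be applied to the angle series.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    norm = np.linalg.norm(accel, axis=1)
    valid = norm >= magnitude_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(valid, -accel[:, 2] / np.where(valid, norm, 1.0), 0.0)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if smooth_s is not None:
        if fs is None:
            raise ValueError("fs required when smoothing")
        theta = uniform_filter1d(theta, max(1, int(round(smooth_s * fs))))
    return TiltSeries(theta=theta, mask=valid)


def tilt_for_active(rec: IMURecording, ann: ActivityAnnotation,
                    magnitude_floor: float = 0.5) -> TiltSeries:
    """Tilt restricted to samples the activity filter kept."""
    if len(ann.keep_mask) != len(rec):
        raise ValueError("annotation and recording lengths differ")
    ts = tilt_angle(rec.accel, magnitude_floor=magnitude_floor)
    return TiltSeries(theta=ts.theta, mask=ts.mask & ann.keep_mask)
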