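"""End-to-end per-recording and per-cohort processing.

One recording flows through: Madgwick gravity removal -> constant-signal
(non-wear) dropout -> two-threshold activity filter -> tilt angle over
active time -> distributional features + windowed sample entropy.  A
cohort of feature vectors then feeds the statistics layer (association
table, VIF, backward elimination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import complexity, features
from .cohort import (EliminationTrace, assign_groups, backward_eliminate,
                     feature_table, vif)
from .complexity import SampEnParams, sampen_signal
from .features import (FEATURE_NAMES, MagnitudeHistogram, QOMEFeatureVector,
                       accel_ratio, gyro_ratio, magnitude_histogram,
                       magnitude_means, tilt_histogram, tilt_moments)
from .orientation import TiltSeries, tilt_for_active
from .preprocess import ActivityAnnotation, FilterConfig, annotate_recording
from .synthetic import IMURecording


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    madgwick_beta: float = 0.1
    tilt_floor: float = 0.5          # m/s^2 validity floor for the tilt angle
    gyro_ratio_literal: bool = False
    sampen_params: dict[str, SampEnParams] = field(
        default_factory=lambda: dict(complexity.DEFAULT_PARAMS))


@dataclass
class SubjectRecord:
    """Everything computed for one recording."""

    subject_id: str
    features: QOMEFeatureVector
    annotation: ActivityAnnotation
    tilt: TiltSeries
    accel_hist: MagnitudeHistogram
    gyro_hist: MagnitudeHistogram
    tilt_hist: MagnitudeHistogram


def _masked_segments(keep: np.ndarray, valid: np.ndarray,
                     segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Restrict annotation segments to samples also valid for tilt; in
    practice validity holes are rare, so segments are used as-is when the
    masks coincide."""
    if np.array_equal(keep, keep & valid):
        return segments
    padded = np.concatenate([[False], keep & valid, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def process_recording(rec: IMURecording,
                      cfg: PipelineConfig | None = None) -> SubjectRecord:
    """Compute the full feature vector for one recording."""
    cfg = cfg or PipelineConfig()
    fs = rec.sampling_rate_hz
    lin, ann = annotate_recording(rec, cfg.filter, beta=cfg.madgwick_beta)
    tilt = tilt_for_active(rec, ann, magnitude_floor=cfg.tilt_floor)

    keep = ann.keep_mask
    lin_mag = np.linalg.norm(lin, axis=1)
    gyro_mag = np.linalg.norm(rec.gyro, axis=1)
    a_hist = magnitude_histogram(lin_mag[keep], "accel")
    g_hist = magnitude_histogram(gyro_mag[keep], "gyro")
    t_hist = tilt_histogram(tilt)
    kurt, skew, var = tilt_moments(tilt)
    a_mean, g_mean = magnitude_means(lin_mag[keep], gyro_mag[keep])

    segs = _masked_segments(keep, tilt.mask, ann.segments)
    se_a = sampen_signal(lin_mag, cfg.sampen_params["accel"], fs, ann.segments)
    se_g = sampen_signal(gyro_mag, cfg.sampen_params["gyro"], fs, ann.segments)
    se_t = sampen_signal(tilt.theta, cfg.sampen_params["tilt"], fs, segs)

    vec = QOMEFeatureVector(
        tilt_kurtosis=kurt, tilt_skewness=skew, tilt_variance=var,
        accel_ratio=accel_ratio(a_hist),
        gyro_ratio=gyro_ratio(g_hist, literal=cfg.gyro_ratio_literal),
        accel_mean=a_mean, gyro_mean=g_mean,
        sampen_accel=se_a.subject_value, sampen_gyro=se_g.subject_value,
        sampen_tilt=se_t.subject_value,
        inactive_fraction=ann.inactive_fraction)
    return SubjectRecord(subject_id=rec.subject_id, features=vec,
                         annotation=ann, tilt=tilt, accel_hist=a_hist,
                         gyro_hist=g_hist, tilt_hist=t_hist)


def cohort_features(recordings: list[IMURecording],
                    cfg: PipelineConfig | None = None
                    ) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    """Feature matrix (one row per subject) for a list of recordings."""
    records = [process_recording(rec, cfg) for rec in recordings]
    df = pd.DataFrame([r.features.to_dict() for r in records],
                      index=[r.subject_id for r in records])
    return df, records


@dataclass
class CohortResult:
    """Association table, elimination trace and diagnostics for a cohort."""

    table: pd.DataFrame
    trace: EliminationTrace
    groups: np.ndarray
    selected_vif: pd.Series | None


def cohort_statistics(feature_df: pd.DataFrame, uefm: np.ndarray,
                      prefilter_alpha: float = 0.05) -> CohortResult:
    """Table-style per-feature statistics plus minimum-AIC model selection.

    ``feature_df`` may include the bookkeeping ``inactive_fraction`` column;
    only the ten movement-experience features enter the analysis.
    """
    uefm = np.asarray(uefm, dtype=float)
    X = feature_df[[c for c in FEATURE_NAMES if c in feature_df.columns]]
    groups = assign_groups(uefm)
    table = feature_table(X, uefm, groups)
    trace = backward_eliminate(X, uefm, prefilter_alpha=prefilter_alpha)
    sel_vif = None
    if len(trace.selected_variables) >= 2:
        ok = np.isfinite(X.to_numpy(float)).all(axis=1)
        sel_vif = vif(X.loc[ok, trace.selected_variables])
    return CohortResult(table=table, trace=trace, groups=groups,
                        selected_vif=sel_vif)


def average_repeated_recordings(feature_df: pd.DataFrame,
                                subject_of: dict[str, str] | None = None,
                                mode: str = "average") -> pd.DataFrame:
    """Collapse repeated wearings to one row per subject.

    ``mode='average'`` (default) averages feature vectors per subject;
    ``mode='pool'`` keeps every recording as an independent observation.
    """
    if mode == "pool" or subject_of is None:
        return feature_df
    if mode != "average":
        raise ValueError("mode must be 'average' or 'pool'")
    key = feature_df.index.map(lambda rid: subject_of.get(rid, rid))
    return feature_df.groupby(key).mean()
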