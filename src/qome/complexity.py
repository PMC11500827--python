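"""Sample Entropy of movement signals.

SampEn(m, r) = -ln( A / B ), where B counts pairs of length-m templates and
A pairs of length-(m+1) templates agreeing within tolerance r under the
Chebyshev (max) distance, self-matches excluded (the Richman-Moorman
estimator).  A lower value means a more regular signal; an irregular,
broadband signal scores higher.

Per-signal defaults (chosen in the source study by a correlation-driven
grid search): acceleration magnitude m=2, r=0.25, N=250, 26 Hz; angular
velocity magnitude m=5, r=0.4, N=750, 52.6 Hz; tilt angle m=3, r=0.35,
N=250, 52.6 Hz.  r is interpreted as a multiple of the per-window SD;
signals are decimated from the native rate by keeping every k-th sample,
and each contiguous active segment is split into non-overlapping windows
of N samples (remainders discarded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats


@dataclass(frozen=True)
class SampEnParams:
    m: int
    r: float        # tolerance, as a fraction of the window SD
    N: int          # segmentation (window) length, samples
    fs: float       # analysis sampling rate, Hz

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.N <= self.m + 1:
            raise ValueError("N must exceed m + 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


ACCEL_SAMPEN = SampEnParams(m=2, r=0.25, N=250, fs=26.0)
GYRO_SAMPEN = SampEnParams(m=5, r=0.4, N=750, fs=52.6)
TILT_SAMPEN = SampEnParams(m=3, r=0.35, N=250, fs=52.6)

DEFAULT_PARAMS = {"accel": ACCEL_SAMPEN, "gyro": GYRO_SAMPEN,
                  "tilt": TILT_SAMPEN}


@dataclass
class SampEnResult:
    per_segment: list[float]      # entropy per window (NaN where undefined)
    subject_value: float          # mean over defined windows (NaN if none)
    n_segments_used: int
    n_segments_undefined: int


def sampen(x: np.ndarray, m: int, r_abs: float) -> float:
    """Sample entropy of one series with an *absolute* tolerance.

    Returns NaN when no template pair matches at length m or m+1 (the
    estimator is undefined there).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series too short for m={m} (need > {m + 1})")
    # templates i = 0..n-m-1 of lengths m and m+1, pairwise Chebyshev
    tpl = sliding_window_view(x, m + 1)          # (n - m, m + 1)
    d = np.abs(tpl[:, 0, None] - tpl[None, :, 0])
    for k in range(1, m):                        # accumulate the max in place
        np.maximum(d, np.abs(tpl[:, k, None] - tpl[None, :, k]), out=d)
    iu = np.triu_indices(tpl.shape[0], k=1)      # exclude self-matches
    b = int(np.count_nonzero(d[iu] <= r_abs))
    np.maximum(d, np.abs(tpl[:, m, None] - tpl[None, :, m]), out=d)
    a = int(np.count_nonzero(d[iu] <= r_abs))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def _decimation_factor(native_fs: float, target_fs: float) -> int:
    k = int(round(native_fs / target_fs))
    if k < 1:
        raise ValueError("analysis rate exceeds the native rate")
    return k


def sampen_signal(x: np.ndarray, params: SampEnParams, native_fs: float,
                  segments: list[tuple[int, int]] | None = None
                  ) -> SampEnResult:
    """Windowed, decimated sample entropy of an active-masked signal.

    ``segments`` are half-open (start, stop) index pairs of contiguous
    active runs at the native rate (the whole series when omitted).  Each
    segment is decimated by keeping every k-th sample, split into
    non-overlapping N-sample windows, and scored with r_abs = r * SD(window).
    """
    x = np.asarray(x, dtype=float)
    if segments is None:
        segments = [(0, x.size)]
    k = _decimation_factor(native_fs, params.fs)
    values: list[float] = []
    for (i, j) in segments:
        xs = x[i:j:k]
        for w in range(xs.size // params.N):
            win = xs[w * params.N:(w + 1) * params.N]
            sd = float(np.std(win))
            values.append(sampen(win, params.m, params.r * sd))
    vals = np.asarray(values, dtype=float)
    defined = vals[np.isfinite(vals)]
    return SampEnResult(per_segment=values,
                        subject_value=(float(defined.mean())
                                       if defined.size else float("nan")),
                        n_segments_used=int(defined.size),
                        n_segments_undefined=int(vals.size - defined.size))


def sampen_grid_search(signals: list[tuple[np.ndarray, list | None]],
                       uefm: np.ndarray, native_fs: float,
                       m_grid=(2, 3, 4, 5), r_grid=(0.2, 0.25, 0.3, 0.35, 0.4),
                       N_grid=(250, 500, 750), fs_grid=(52.6, 26.0, 13.0),
                       ) -> tuple[SampEnParams, pd.DataFrame]:
    """Pick the (m, r, N, fs) combination whose subject-level entropy is
    most strongly Pearson-correlated (by |r|) with the impairment score.

    ``signals`` holds one (series, segments) pair per subject.  Rows where
    every subject's entropy is undefined, or where the entropy has zero
    variance, are marked invalid and skipped.
    """
    uefm = np.asarray(uefm, dtype=float)
    if len(signals) < 3:
        raise ValueError("grid search needs at least 3 subjects")
    rows = []
    for m in m_grid:
        for r in r_grid:
            for N in N_grid:
                for fs in fs_grid:
                    try:
                        params = SampEnParams(m=m, r=r, N=N, fs=fs)
                    except ValueError:
                        continue
                    vals = np.array([sampen_signal(x, params, native_fs,
                                                   seg).subject_value
                                     for (x, seg) in signals])
                    ok = np.isfinite(vals)
                    if ok.sum() < 3 or np.std(vals[ok]) == 0:
                        rows.append({"m": m, "r": r, "N": N, "fs": fs,
                                     "pearson_r": np.nan, "p_value": np.nan,
                                     "n_subjects": int(ok.sum()),
                                     "valid": False})
                        continue
                    pr, p = stats.pearsonr(vals[ok], uefm[ok])
                    rows.append({"m": m, "r": r, "N": N, "fs": fs,
                                 "pearson_r": pr, "p_value": p,
                                 "n_subjects": int(ok.sum()), "valid": True})
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError("no parameter combination produced a defined, "
                         "non-degenerate entropy across subjects")
    best = valid.loc[valid["pearson_r"].abs().idxmax()]
    return (SampEnParams(m=int(best["m"]), r=float(best["r"]),
                         N=int(best["N"]), fs=float(best["fs"])), table)
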