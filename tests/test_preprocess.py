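"""Gravity removal and activity-filter behavior against enumeration oracles."""

import numpy as np
import pytest

from qome.preprocess import (FilterConfig, activity_filter,
                             drop_constant_periods, grid_search_thresholds,
                             remove_gravity)
from qome.synthetic import (GRAVITY, IMURecording, generate_cohort,
                            generate_recording, profile_from_uefm)
from tests.conftest import make_static_recording

FS = 52.6


def _oracle_mask(u, window, theta_U):
    """Direct enumeration of the trailing-window mean and threshold."""
    n = len(u)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - window + 1)
        keep[i] = np.mean(u[lo:i + 1]) >= theta_U
    return keep


class TestRemoveGravity:
    def test_static_residual_small(self, static_recording):
        lin = remove_gravity(static_recording)
        post = int(5 * FS)
        assert np.linalg.norm(lin[post:], axis=1).max() < 0.1

    def test_rotation_static_at_both_ends(self):
        # 90 deg rotation about X between two static phases, exact rates
        n = int(40 * FS)
        t = np.arange(n) / FS
        th = np.clip((t - 15.0) / 10.0, 0.0, 1.0) * (np.pi / 2)
        ghat = np.column_stack([np.zeros(n), np.sin(th), -np.cos(th)])
        dghat = np.gradient(ghat, 1 / FS, axis=0)
        omega = np.cross(dghat, ghat)
        rec = IMURecording("rot", FS, t, GRAVITY * ghat, np.degrees(omega))
        lin = remove_gravity(rec)
        mag = np.linalg.norm(lin, axis=1)
        assert mag[int(5 * FS):int(14 * FS)].max() < 0.1
        assert mag[int(28 * FS):].max() < 0.1

    def test_sinusoidal_burst_recovered(self):
        n = int(30 * FS)
        t = np.arange(n) / FS
        amp, f = 2.5, 1.5
        accel = np.tile([0.0, 0.0, -GRAVITY], (n, 1))
        accel[:, 0] += amp * np.sin(2 * np.pi * f * t)
        rec = IMURecording("sin", FS, t, accel, np.zeros((n, 3)))
        lin = remove_gravity(rec)
        seg = slice(int(10 * FS), n)
        quad = lin[seg, 0] * np.exp(-2j * np.pi * f * t[seg])
        recovered = 2 * np.abs(quad.mean())
        assert abs(recovered - amp) / amp < 0.10

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            remove_gravity(make_static_recording((0, 0, -GRAVITY),
                                                 duration_s=2.0))


class TestDropConstantPeriods:
    def _with_constant_block(self, block_s):
        rng = np.random.default_rng(0)
        n = int(600 * FS)
        t = np.arange(n) / FS
        accel = np.tile([0.0, 0.0, -GRAVITY], (n, 1)) + rng.normal(0, 0.05, (n, 3))
        gyro = rng.normal(0, 0.5, (n, 3))
        i0, i1 = int(100 * FS), int((100 + block_s) * FS)
        accel[i0:i1] = accel[i0]
        gyro[i0:i1] = gyro[i0]
        return IMURecording("c", FS, t, accel, gyro), i0, i1

    def test_four_minute_block_dropped(self):
        rec, i0, i1 = self._with_constant_block(240)
        keep = drop_constant_periods(rec, dropout_min_s=180.0)
        assert not keep[i0:i1].any()
        assert keep[:i0].all() and keep[i1:].all()

    def test_two_minute_block_kept(self):
        rec, i0, i1 = self._with_constant_block(120)
        keep = drop_constant_periods(rec, dropout_min_s=180.0)
        assert keep.all()

    def test_varying_signal_untouched(self, mid_profile_recording):
        _, rec = mid_profile_recording
        assert drop_constant_periods(rec, dropout_min_s=180.0).all()


class TestActivityFilter:
    def test_all_zero_is_fully_inactive(self):
        cfg = FilterConfig()
        ann = activity_filter(np.zeros((int(60 * FS), 3)), cfg, FS)
        assert ann.inactive_fraction == 1.0
        assert ann.segments == []

    def test_square_wave_matches_enumeration_oracle(self):
        # 20 s on at 0.3 G alternating with 20 s off
        cfg = FilterConfig(theta_u=0.1, theta_U=0.1, window_D_s=10.0)
        n = int(200 * FS)
        t = np.arange(n) / FS
        on = (t // 20).astype(int) % 2 == 1
        mag = np.where(on, 0.3 * GRAVITY, 0.0)
        ann = activity_filter(mag, cfg, FS)
        window = int(round(10.0 * FS))
        expected = _oracle_mask((mag > 0.1 * GRAVITY).astype(float),
                                window, 0.1)
        assert np.array_equal(ann.keep_mask, expected)
        # segments partition exactly the kept samples
        covered = np.zeros(n, dtype=bool)
        for (i, j) in ann.segments:
            assert not covered[i:j].any()
            covered[i:j] = True
        assert np.array_equal(covered, ann.keep_mask)

    def test_zero_threshold_keeps_everything(self):
        cfg = FilterConfig(theta_U=0.0)
        ann = activity_filter(np.zeros(int(60 * FS)), cfg, FS)
        assert ann.keep_mask.all()
        assert ann.inactive_fraction == 0.0

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            activity_filter(np.zeros(10), FilterConfig(window_D_s=10.0), FS)

    @pytest.mark.parametrize("theta_U", [0.05, 0.1, 0.2, 0.3])
    def test_monotone_in_theta_U(self, mid_profile_recording, theta_U):
        _, rec = mid_profile_recording
        lin = remove_gravity(rec)
        lo = activity_filter(lin, FilterConfig(theta_U=theta_U), FS)
        hi = activity_filter(lin, FilterConfig(theta_U=theta_U + 0.05), FS)
        assert hi.total_active_s <= lo.total_active_s

    @pytest.mark.parametrize("theta_u", [0.05, 0.1, 0.2])
    def test_monotone_in_theta_u(self, mid_profile_recording, theta_u):
        _, rec = mid_profile_recording
        lin = remove_gravity(rec)
        lo = activity_filter(lin, FilterConfig(theta_u=theta_u), FS)
        hi = activity_filter(lin, FilterConfig(theta_u=theta_u + 0.05), FS)
        assert hi.u.sum() <= lo.u.sum()

    def test_idempotent_reapplication(self, mid_profile_recording):
        _, rec = mid_profile_recording
        lin = remove_gravity(rec)
        cfg = FilterConfig()
        a = activity_filter(lin, cfg, FS)
        b = activity_filter(lin, cfg, FS)
        assert np.array_equal(a.keep_mask, b.keep_mask)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def small_cohort_mags(self):
        cohort = generate_cohort(8, seed=21, duration_s=420.0)
        mags = [np.linalg.norm(remove_gravity(rec), axis=1)
                for _, rec in cohort]
        uefm = np.array([p.uefm for p, _ in cohort], float)
        return mags, uefm

    def test_surface_is_6x6(self, small_cohort_mags):
        mags, uefm = small_cohort_mags
        res = grid_search_thresholds(mags, uefm, FS)
        assert len(res.table) == 36
        assert res.surface.shape == (6, 6)

    def test_selected_pair_has_negative_correlation(self, small_cohort_mags):
        mags, uefm = small_cohort_mags
        res = grid_search_thresholds(mags, uefm, FS)
        assert res.selected is not None
        tu, tU = res.selected
        row = res.table[(res.table.theta_u == tu)
                        & (res.table.theta_U == tU)].iloc[0]
        assert row.pearson_r < 0
        assert row.p_value < 0.05

    def test_identical_recordings_yield_null_selection(self):
        mag = np.abs(np.sin(np.arange(int(120 * FS)) / FS)) * 2.0
        mags = [mag.copy() for _ in range(4)]
        uefm = np.array([10.0, 25.0, 40.0, 60.0])
        with pytest.warns(UserWarning):
            res = grid_search_thresholds(mags, uefm, FS)
        assert res.selected is None
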