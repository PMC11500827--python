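"""Sample Entropy kernel against a brute-force oracle, analytic limits,
and the windowed per-signal wrapper."""

import numpy as np
import pytest

from qome.complexity import (ACCEL_SAMPEN, GYRO_SAMPEN, TILT_SAMPEN,
                             SampEnParams, sampen, sampen_grid_search,
                             sampen_signal)


class TestKernel:
    def test_matches_bruteforce_on_random_series(self, sampen_oracle):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(12, 61))
            m = int(rng.integers(1, 4))
            x = rng.normal(0, 1, n)
            r = float(rng.uniform(0.05, 0.6))
            got = sampen(x, m, r)
            want = sampen_oracle(x, m, r)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == want  # identical counts, identical log

    def test_constant_series_is_zero(self):
        assert sampen(np.full(50, 3.0), 2, 0.1) == 0.0

    def test_periodic_pattern_matches_oracle(self, sampen_oracle):
        x = np.array([1, 2, 3] * 4, dtype=float)
        assert sampen(x, 2, 0.1) == sampen_oracle(x, 2, 0.1)

    def test_noise_more_entropic_than_sinusoid(self):
        rng = np.random.default_rng(1)
        t = np.arange(300)
        wins = 0
        for _ in range(50):
            noise = rng.uniform(-1, 1, 300)
            sine = np.sin(2 * np.pi * t / 30 + rng.uniform(0, 2 * np.pi))
            se_n = sampen(noise, 2, 0.2 * np.std(noise))
            se_s = sampen(sine, 2, 0.2 * np.std(sine))
            wins += int(se_n > se_s)
        assert wins >= 45  # sign test, overwhelming majority

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sampen(np.arange(3.0), 2, 0.1)

    def test_undefined_when_no_matches(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        assert np.isnan(sampen(x, 2, 1e-12))


class TestSampEnSignal:
    def test_default_parameter_sets(self):
        assert (ACCEL_SAMPEN.m, ACCEL_SAMPEN.r, ACCEL_SAMPEN.N,
                ACCEL_SAMPEN.fs) == (2, 0.25, 250, 26.0)
        assert (GYRO_SAMPEN.m, GYRO_SAMPEN.r, GYRO_SAMPEN.N,
                GYRO_SAMPEN.fs) == (5, 0.4, 750, 52.6)
        assert (TILT_SAMPEN.m, TILT_SAMPEN.r, TILT_SAMPEN.N,
                TILT_SAMPEN.fs) == (3, 0.35, 250, 52.6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SampEnParams(m=0, r=0.2, N=100, fs=52.6)
        with pytest.raises(ValueError):
            SampEnParams(m=2, r=0.2, N=3, fs=52.6)

    def test_scale_invariance_with_sd_relative_tolerance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 1000)
        params = SampEnParams(m=2, r=0.25, N=250, fs=52.6)
        a = sampen_signal(x, params, native_fs=52.6)
        b = sampen_signal(1000.0 * x, params, native_fs=52.6)
        assert a.subject_value == pytest.approx(b.subject_value, abs=1e-12)

    def test_decimation_keeps_every_kth_sample(self, sampen_oracle):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 500)
        params = SampEnParams(m=2, r=0.25, N=100, fs=26.0)
        res = sampen_signal(x, params, native_fs=52.6)
        xs = x[::2]
        expected = []
        for w in range(len(xs) // 100):
            win = xs[w * 100:(w + 1) * 100]
            expected.append(sampen_oracle(win, 2, 0.25 * np.std(win)))
        assert res.per_segment == pytest.approx(expected)
        assert res.subject_value == pytest.approx(np.nanmean(expected))

    def test_short_segments_give_no_windows(self):
        res = sampen_signal(np.zeros(100),
                            SampEnParams(m=2, r=0.25, N=250, fs=52.6),
                            native_fs=52.6)
        assert res.n_segments_used == 0
        assert np.isnan(res.subject_value)

    def test_segments_respected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 1000)
        params = SampEnParams(m=2, r=0.25, N=200, fs=52.6)
        whole = sampen_signal(x, params, native_fs=52.6,
                              segments=[(0, 400), (400, 1000)])
        assert len(whole.per_segment) == 2 + 3

    def test_monotone_response_to_complexity_mixing(self):
        """Subject-level entropy ranks with the oscillation/broadband
        mixing weight across 30 synthetic subjects."""
        from scipy.signal import lfilter
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        params = SampEnParams(m=3, r=0.35, N=250, fs=52.6)
        cs = np.linspace(0.05, 0.95, 30)
        vals = []
        for c in cs:
            t = np.arange(2000) / 52.6
            osc = np.sqrt(2) * np.sin(2 * np.pi * 0.5 * t
                                      + rng.uniform(0, 2 * np.pi))
            e = rng.normal(0, 1, 2200)
            broad = lfilter([1.0], [1.0, -0.95], e)[200:]
            broad /= broad.std()
            x = 8.0 * ((1 - c) * osc + c * broad)
            vals.append(sampen_signal(x, params, 52.6).subject_value)
        rho = spearmanr(cs, vals).statistic
        assert rho >= 0.8


class TestGridSearch:
    def _signals(self, n=6, complexity=None, seed=7):
        from scipy.signal import lfilter

        rng = np.random.default_rng(seed)
        signals, uefm = [], []
        for i in range(n):
            c = complexity[i] if complexity is not None else rng.uniform(0, 1)
            t = np.arange(1500) / 52.6
            osc = np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))
            e = rng.normal(0, 1, 1700)
            broad = lfilter([1.0], [1.0, -0.95], e)[200:]
            broad /= broad.std()
            signals.append((8 * ((1 - c) * osc + c * broad), None))
            uefm.append(10 + 55 * c)
        return signals, np.array(uefm)

    def test_singleton_grid_returns_those_params(self):
        signals, uefm = self._signals()
        best, table = sampen_grid_search(signals, uefm, native_fs=52.6,
                                         m_grid=(3,), r_grid=(0.35,),
                                         N_grid=(250,), fs_grid=(52.6,))
        assert best == SampEnParams(m=3, r=0.35, N=250, fs=52.6)
        assert len(table) == 1

    def test_identical_signals_raise(self):
        x = np.sin(np.arange(1500) / 10.0)
        signals = [(x.copy(), None) for _ in range(4)]
        with pytest.raises(ValueError):
            sampen_grid_search(signals, np.array([10, 20, 40, 60.0]),
                               native_fs=52.6, m_grid=(2,), r_grid=(0.25,),
                               N_grid=(250,), fs_grid=(52.6,))

    def test_slow_complexity_prefers_lower_rate(self):
        """Complexity injected at slow timescales and masked by a fast
        periodic movement component is exposed by down-sampling, so the
        search prefers the reduced rate."""
        from scipy.signal import lfilter

        rng = np.random.default_rng(0)
        signals, uefm = [], []
        for c in np.linspace(0.05, 0.95, 10):
            n = 8000
            t = np.arange(n) / 52.6
            osc = np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
            e = rng.normal(0, 1, n + 400)
            slow = lfilter([1.0], [1.0, -0.999], e)[400:]
            slow /= slow.std()
            tone = 4.0 * np.sin(2 * np.pi * 12.0 * t
                                + rng.uniform(0, 2 * np.pi))
            signals.append((8 * ((1 - c) * osc + c * slow) + tone, None))
            uefm.append(10 + 55 * c)
        best, table = sampen_grid_search(signals, np.array(uefm),
                                         native_fs=52.6, m_grid=(3,),
                                         r_grid=(0.35,), N_grid=(250,),
                                         fs_grid=(52.6, 13.0))
        assert best.fs == 13.0
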