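import numpy as np
import pytest

from qome.synthetic import GRAVITY, IMURecording


def sampen_bruteforce(x, m, r_abs):
    """Independent O(N^2) reference Sample Entropy, written from the
    definition with explicit loops: templates i = 0..N-m-1, pairwise
    Chebyshev distance, self-matches excluded, -ln(A/B)."""
    x = [float(v) for v in x]
    n = len(x)
    count_m = 0
    count_m1 = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                d = max(d, abs(x[i + k] - x[j + k]))
            if d <= r_abs:
                count_m += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return float("nan")
    return -np.log(count_m1 / count_m)


@pytest.fixture(scope="session")
def sampen_oracle():
    return sampen_bruteforce


def make_static_recording(accel_vec, duration_s=20.0, fs=52.6,
                          noise_sd=0.0, seed=0):
    """Recording with a constant acceleration vector and zero rates."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    accel = np.tile(np.asarray(accel_vec, float), (n, 1))
    if noise_sd:
        accel = accel + rng.normal(0, noise_sd, (n, 3))
    return IMURecording("static", fs, t, accel, np.zeros((n, 3)))


@pytest.fixture(scope="session")
def static_recording():
    return make_static_recording((0.0, 0.0, -GRAVITY))


@pytest.fixture(scope="session")
def mid_profile_recording():
    """One mid-severity synthetic recording shared across tests."""
    from qome.synthetic import generate_recording, profile_from_uefm

    rng = np.random.default_rng(42)
    profile = profile_from_uefm("mid", 40, rng)
    return profile, generate_recording(profile, duration_s=900.0)
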