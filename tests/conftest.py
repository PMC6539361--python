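import numpy as np
import pytest

from sitlight import posture, synth


@pytest.fixture(scope="session")
def small_posture_model():
    """A quickly trained 7-class posture network shared across tests."""
    X, y = synth.gen_pressure_dataset(n_frames=60, seed=0)
    return posture.train_lm(X, y, n_hidden=8, seed=0, max_iter=60)


@pytest.fixture(scope="session")
def calibration():
    from sitlight.bcg import CalibrationRange
    return CalibrationRange(hrv_min=15.0, hrv_max=80.0)


def mad_oracle(x: np.ndarray, w: int) -> np.ndarray:
    """Brute-force per-sample moving MAD with truncated centred windows."""
    n = x.size
    half = w // 2
    out = np.empty(n)
    for k in range(n):
        seg = x[max(0, k - half): min(n, k - half + w)]
        mu = seg.mean()
        out[k] = np.abs(seg - mu).mean()
    return out


def moving_max_oracle(env: np.ndarray, w: int) -> list[int]:
    """Exhaustive all-windows moving-maximum beat picking.

    A sample is a candidate iff it equals the maximum of every length-w
    window that contains it; candidates then pass an earliest-first
    refractory gap of w samples.
    """
    n = env.size
    candidates = []
    for k in range(n):
        if env[k] <= 0:
            continue
        starts = range(max(0, k - w + 1), min(k, n - w) + 1)
        if not starts:
            starts = [0]
        if all(env[k] == env[s:s + w].max() for s in starts):
            candidates.append(k)
    kept = []
    for k in candidates:
        if not kept or k - kept[-1] >= w:
            kept.append(k)
    return kept
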