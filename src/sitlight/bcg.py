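"""Ballistocardiogram processing: denoising, beat detection, IBI and HRV.

The chain turns a raw single-channel seat-sensor (BCG) series into validated
inter-beat intervals and a running heart-rate-variability estimate:

1. ``wavelet_denoise`` — Haar wavelet band-pass: keep only the level-4
   detail band (fs/32 .. fs/16, i.e. 8-16 Hz at the default 256 Hz), which
   brackets the oscillatory burst each heartbeat produces and suppresses the
   low-frequency respiratory drift.  The undecimated (stationary) transform
   is used so that the reconstruction is shift-invariant: a decimated DWT
   detail is piecewise constant on 2^4-sample blocks, which quantises beat
   timing to tens of milliseconds and dominates the IBI error budget.
2. ``moving_mad`` — a moving mean-absolute-deviation envelope that
   emphasises the instantaneous amplitude bursts at each beat.  The default
   window (150 ms) matches the beat-complex support, so the envelope peaks
   sharply at the beat instead of plateauing across it.
3. ``detect_beats`` — moving-maximum peak picking in a 400 ms window.
4. ``compute_ibis`` — successive differences with a physiological validity
   gate.
5. ``update_hrv`` — the per-beat recursive estimator

       HRV_N <- ((N-1) * HRV_N + |IBI - IBI_N|) / N
       IBI_N <- ((N-1) * IBI_N + IBI) / N          (N = 40 by default)

   where HRV_N is updated with the *pre-update* IBI_N.  This is an
   exponentially weighted mean absolute deviation of the IBIs, updated once
   per heartbeat, not a windowed SDNN.

``sdnn`` and ``calibrate_range`` implement the per-user calibration: SDNN of
one minute of relaxed slow breathing gives the user's maximum HRV, SDNN of
the minute following physical exercise gives the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import maximum_filter1d

from .errors import (
    CalibrationError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "RawBCG",
    "HeartbeatEnvelope",
    "IBISeries",
    "HRVState",
    "CalibrationRange",
    "wavelet_denoise",
    "band_reconstructions",
    "moving_mad",
    "detect_beats",
    "compute_ibis",
    "update_hrv",
    "run_hrv",
    "sdnn",
    "calibrate_range",
    "process_bcg",
    "match_beats",
    "mean_ibi_error",
]

DEFAULT_IBI_GATE = (300.0, 1500.0, 0.30)
HAAR_LEVEL = 4


@dataclass(frozen=True)
class RawBCG:
    """A uniformly sampled single-channel BCG series."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidArgumentError("BCG series must be 1-D with length >= 2")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class HeartbeatEnvelope:
    """Nonnegative heartbeat envelope, same sampling grid as its source."""

    values: np.ndarray
    fs: float
    window_ms: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class IBISeries:
    """Inter-beat intervals paired with the beats that delimit them.

    ``ibis_ms[k]`` is the interval between ``beat_times[k]`` and
    ``beat_times[k+1]`` in milliseconds; ``valid[k]`` marks whether it passed
    the validity gate.
    """

    beat_times: np.ndarray           # seconds, strictly increasing
    ibis_ms: np.ndarray              # len == len(beat_times) - 1 (or 0)
    valid: np.ndarray                # bool, same length as ibis_ms

    def __post_init__(self):
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))
        object.__setattr__(self, "ibis_ms", np.asarray(self.ibis_ms, dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise InvalidArgumentError("beat_times must be strictly increasing")
        expected = max(self.beat_times.size - 1, 0)
        if self.ibis_ms.size != expected or self.valid.size != expected:
            raise InvalidArgumentError("ibis/valid length must be n_beats - 1")

    def __len__(self) -> int:
        return int(self.ibis_ms.size)

    @property
    def valid_ibis(self) -> np.ndarray:
        return self.ibis_ms[self.valid]

    @property
    def span_s(self) -> float:
        if self.beat_times.size < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])

    @classmethod
    def empty(cls) -> "IBISeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool))


@dataclass(frozen=True)
class HRVState:
    """State of the recursive (IBI_N, HRV_N) estimator.

    The estimate is flagged as warm-up until ``n_seen`` reaches the window
    length (40 valid beats by default).
    """

    ibi40: float = 0.0
    hrv40: float = 0.0
    n_seen: int = 0
    window: int = 40

    @property
    def warmed_up(self) -> bool:
        return self.n_seen >= self.window


@dataclass(frozen=True)
class CalibrationRange:
    """Per-user HRV range: SDNN while relaxed (max) vs after exercise (min)."""

    hrv_min: float
    hrv_max: float

    def __post_init__(self):
        if not (self.hrv_max > self.hrv_min >= 0):
            raise InvalidArgumentError("calibration requires hrv_max > hrv_min >= 0")


# ---------------------------------------------------------------------------
# wavelet denoising


def _padded_length(n: int) -> int:
    m = 2 ** HAAR_LEVEL
    return n + (-n) % m


def band_reconstructions(raw: RawBCG) -> dict[str, np.ndarray]:
    """Reconstruct every Haar sub-band of a 4-level decomposition separately.

    Uses the undecimated (stationary) transform, so each band is a
    shift-invariant, same-rate time series.  Returns arrays keyed
    ``a4, d4, d3, d2, d1``, each trimmed to the input length; their sum
    equals the input (linearity of the inverse transform).
    """
    x = raw.values
    n = x.size
    if n < 2 ** HAAR_LEVEL:
        raise InvalidArgumentError(
            f"signal shorter than one level-{HAAR_LEVEL} support ({2**HAAR_LEVEL} samples)"
        )
    xp = np.pad(x, (0, _padded_length(n) - n), mode="edge")
    coeffs = pywt.swt(xp, "haar", level=HAAR_LEVEL, norm=True)
    # coeffs[0] is the coarsest level: (cA4, cD4), ..., coeffs[-1] = (cA1, cD1)
    out: dict[str, np.ndarray] = {}

    def rec(keep_level: int, keep_detail: bool) -> np.ndarray:
        kept = []
        for i, (ca, cd) in enumerate(coeffs):
            ca_k = ca if (i == keep_level and not keep_detail) else np.zeros_like(ca)
            cd_k = cd if (i == keep_level and keep_detail) else np.zeros_like(cd)
            kept.append((ca_k, cd_k))
        return pywt.iswt(kept, "haar", norm=True)[:n]

    out["a4"] = rec(0, False)
    for i in range(HAAR_LEVEL):
        out[f"d{HAAR_LEVEL - i}"] = rec(i, True)
    return out


def wavelet_denoise(raw: RawBCG) -> RawBCG:
    """Band-pass the BCG by keeping only the level-4 Haar detail band.

    All other detail and approximation coefficients are zeroed before the
    inverse transform; the result has the same length and rate as the input
    (the signal is edge-padded to a multiple of 2**4 and trimmed back).
    """
    d4 = band_reconstructions(raw)["d4"]
    return RawBCG(d4, raw.fs)


# ---------------------------------------------------------------------------
# envelope and beat detection


def moving_mad(signal: RawBCG, window_ms: float = 150.0) -> HeartbeatEnvelope:
    """Moving mean absolute deviation around the moving window mean.

    ``out[k] = mean(|x_j - mean(x_window)|)`` over a centred window of
    ``window_ms``; windows are truncated (not padded) at the series edges.
    For an even sample count the window extends one sample further to the
    left of the centre.
    """
    if window_ms <= 0:
        raise InvalidArgumentError("window_ms must be positive")
    x = signal.values
    n = x.size
    w = int(round(window_ms * signal.fs / 1000.0))
    if w < 2:
        raise InvalidArgumentError("window must span at least 2 samples")
    half = w // 2  # samples before the centre
    out = np.empty(n)
    k0, k1 = half, n - (w - half) + 1  # centres with a full window
    if k1 > k0 and n >= w:
        win = sliding_window_view(x, w)
        mu = win.mean(axis=1)
        out[k0:k1] = np.abs(win - mu[:, None]).mean(axis=1)
    else:
        k0, k1 = n, n  # force edge handling everywhere
    for k in list(range(0, min(k0, n))) + list(range(max(k1, 0), n)):
        seg = x[max(0, k - half): min(n, k - half + w)]
        out[k] = np.abs(seg - seg.mean()).mean()
    return HeartbeatEnvelope(out, signal.fs, window_ms)


def detect_beats(env: HeartbeatEnvelope, window_ms: float = 400.0) -> np.ndarray:
    """Moving-maximum beat picking.

    A sample is a beat iff it is the maximum of every ``window_ms`` window
    that contains it (equivalently, of its +-window neighbourhood).  Ties are
    broken by the earliest sample and a refractory gap of one full window is
    enforced, so no two beats are closer than ``window_ms``.  A flat
    (all-zero) envelope yields no beats.
    """
    x = env.values
    if x.size == 0:
        return np.empty(0)
    if np.any(x < 0):
        raise InvalidArgumentError("envelope must be nonnegative")
    w = max(int(round(window_ms * env.fs / 1000.0)), 1)
    neighbourhood_max = maximum_filter1d(x, size=2 * w - 1, mode="nearest")
    candidates = np.flatnonzero((x == neighbourhood_max) & (x > 0))
    kept: list[int] = []
    for i in candidates:
        if not kept or i - kept[-1] >= w:
            kept.append(int(i))
    return np.asarray(kept, dtype=float) / env.fs


# ---------------------------------------------------------------------------
# IBIs, HRV, calibration


def compute_ibis(
    beat_times: np.ndarray,
    gate: tuple[float, float, float] = DEFAULT_IBI_GATE,
) -> IBISeries:
    """Successive beat differences in ms with a validity gate.

    An IBI is valid when it lies within ``[gate_lo, gate_hi]`` ms and within
    ``+-rel_jump`` of the previous *valid* IBI (the first in-range IBI is
    accepted unconditionally).  Fewer than two beats give an empty series.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise InvalidArgumentError("beat_times must be strictly increasing")
    if beat_times.size < 2:
        return IBISeries(beat_times, np.empty(0), np.empty(0, dtype=bool))
    lo, hi, rel = gate
    ibis = np.diff(beat_times) * 1000.0
    valid = np.zeros(ibis.size, dtype=bool)
    prev: float | None = None
    for k, ibi in enumerate(ibis):
        ok = lo <= ibi <= hi
        if ok and prev is not None:
            ok = abs(ibi - prev) <= rel * prev
        valid[k] = ok
        if ok:
            prev = ibi
    return IBISeries(beat_times, ibis, valid)


def update_hrv(state: HRVState, ibi_ms: float, valid: bool = True) -> HRVState:
    """One per-beat step of the recursive (IBI_N, HRV_N) estimator.

    HRV_N is updated first, using the pre-update IBI_N; then IBI_N.  An
    invalid IBI is rejected and leaves the state unchanged.  An empty state
    is seeded with the first valid IBI (hrv40 = 0).
    """
    if not valid:
        return state
    if not np.isfinite(ibi_ms) or ibi_ms <= 0:
        raise InvalidArgumentError("ibi must be a positive finite value in ms")
    n = state.window
    if state.n_seen == 0:
        return replace(state, ibi40=float(ibi_ms), hrv40=0.0, n_seen=1)
    hrv = ((n - 1) * state.hrv40 + abs(ibi_ms - state.ibi40)) / n
    ibi40 = ((n - 1) * state.ibi40 + ibi_ms) / n
    return replace(state, ibi40=ibi40, hrv40=hrv, n_seen=state.n_seen + 1)


def run_hrv(ibis: IBISeries, window: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Run the recursive estimator over a series; returns (times, hrv40 trace).

    One entry per valid IBI, timestamped at the closing beat.
    """
    state = HRVState(window=window)
    times, trace = [], []
    for k in range(len(ibis)):
        if ibis.valid[k]:
            state = update_hrv(state, float(ibis.ibis_ms[k]))
            times.append(float(ibis.beat_times[k + 1]))
            trace.append(state.hrv40)
    return np.asarray(times), np.asarray(trace)


def sdnn(ibis: IBISeries) -> float:
    """Population standard deviation of the valid IBIs, in ms."""
    v = ibis.valid_ibis
    if v.size < 2:
        raise InsufficientDataError("sdnn needs at least 2 valid IBIs")
    return float(np.std(v))


def calibrate_range(relax_ibis: IBISeries, exercise_ibis: IBISeries,
                    min_span_s: float = 60.0) -> CalibrationRange:
    """Per-user HRV range from the two-phase protocol.

    ``hrv_max`` is the SDNN of one minute of relaxed slow breathing,
    ``hrv_min`` the SDNN of the minute following physical exercise.  An
    inverted range signals an unusable protocol run.
    """
    for name, s in (("relax", relax_ibis), ("exercise", exercise_ibis)):
        if s.span_s < min_span_s:
            raise InsufficientDataError(
                f"{name} series spans {s.span_s:.1f} s < {min_span_s:.0f} s")
    hrv_max = sdnn(relax_ibis)
    hrv_min = sdnn(exercise_ibis)
    if hrv_max <= hrv_min:
        raise CalibrationError(
            f"relax SDNN ({hrv_max:.1f} ms) must exceed exercise SDNN ({hrv_min:.1f} ms)")
    return CalibrationRange(hrv_min=hrv_min, hrv_max=hrv_max)


def process_bcg(
    raw: RawBCG,
    mad_window_ms: float = 150.0,
    beat_window_ms: float = 400.0,
    gate: tuple[float, float, float] = DEFAULT_IBI_GATE,
) -> IBISeries:
    """Full pipeline: denoise -> envelope -> beats -> validated IBIs."""
    denoised = wavelet_denoise(raw)
    env = moving_mad(denoised, mad_window_ms)
    beats = detect_beats(env, beat_window_ms)
    return compute_ibis(beats, gate)


# ---------------------------------------------------------------------------
# evaluation against ground truth


def match_beats(detected: np.ndarray, reference: np.ndarray,
                tol_s: float = 0.15) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected to reference beats.

    Each reference beat is matched to the nearest unused detected beat within
    ``tol_s``.  Returns (reference_index, detected_index) pairs.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ri, rt in enumerate(reference):
        if detected.size == 0:
            break
        d = np.abs(detected - rt)
        d[used] = np.inf
        di = int(np.argmin(d))
        if d[di] <= tol_s:
            used[di] = True
            pairs.append((ri, di))
    return pairs


def mean_ibi_error(detected: np.ndarray, reference: np.ndarray,
                   tol_s: float = 0.15) -> tuple[float, int]:
    """Mean absolute IBI error (ms) over consecutively matched beat pairs.

    Only intervals whose two delimiting beats are matched to *consecutive*
    reference beats contribute, so a missed or spurious beat drops the
    affected intervals instead of corrupting them.  Returns (mae_ms, count).
    """
    pairs = dict(match_beats(detected, reference, tol_s))
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    errs = []
    for ri in range(len(reference) - 1):
        if ri in pairs and (ri + 1) in pairs:
            ibi_det = (detected[pairs[ri + 1]] - detected[pairs[ri]]) * 1000.0
            ibi_ref = (reference[ri + 1] - reference[ri]) * 1000.0
            errs.append(abs(ibi_det - ibi_ref))
    if not errs:
        return float("nan"), 0
    return float(np.mean(errs)), len(errs)
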