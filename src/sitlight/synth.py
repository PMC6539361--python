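"""Synthetic sensor streams with ground truth.

Every downstream stage (BCG pipeline, posture classifier, light mappings,
session state machine) is exercised on data from this module, so each
generator returns the ground truth it embedded: exact beat times for the BCG,
archetype labels for pressure frames, expected mode transitions for session
scripts.

The BCG model is a train of damped-oscillation beat wavelets (a
Gaussian-windowed 15 Hz sinusoid with ~150 ms support — a band-limited burst
like the one each heart contraction imprints on a seat sensor) plus a
low-frequency respiratory sine and additive white Gaussian noise.  It makes
no attempt at anatomical I/J/K-wave morphology; its purpose is a controllable
signal whose true beat times are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bcg import CalibrationRange, IBISeries, RawBCG
from .errors import InvalidArgumentError

__all__ = [
    "BCGGroundTruth",
    "PostureArchetype",
    "SessionScript",
    "ARCHETYPE_LABELS",
    "default_archetypes",
    "gen_bcg",
    "gen_ibi_stream",
    "gen_pressure",
    "gen_pressure_dataset",
    "gen_session_script",
]

BEAT_CARRIER_HZ = 15.0     # lands in the level-4 Haar detail band at fs=256
BEAT_SUPPORT_S = 0.150
BEAT_SIGMA_S = BEAT_SUPPORT_S / 6.0


@dataclass(frozen=True)
class BCGGroundTruth:
    beat_times: np.ndarray        # seconds, strictly increasing
    resp_rate: float              # Hz
    noise_sd: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "beat_times",
                           np.asarray(self.beat_times, dtype=float))
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise InvalidArgumentError("beat_times must be strictly increasing")


@dataclass(frozen=True)
class PostureArchetype:
    """One sitting-posture class: mean load on the six seat sensors.

    Channel layout mirrors the physical pad: f1..f3 are the left column
    (front, middle, rear), f4..f6 the right column.
    """

    label: str
    mean_pressures: np.ndarray    # 6 nonnegative sensor units
    spread: float                 # per-channel Gaussian noise SD

    def __post_init__(self):
        mp = np.asarray(self.mean_pressures, dtype=float)
        object.__setattr__(self, "mean_pressures", mp)
        if mp.shape != (6,) or np.any(mp < 0):
            raise InvalidArgumentError("mean_pressures must be 6 nonnegative values")
        if self.spread < 0:
            raise InvalidArgumentError("spread must be nonnegative")


ARCHETYPE_LABELS = ("upright", "lean_left", "lean_right", "lean_forward",
                    "slouch_back", "edge_sit", "empty")

_ARCHETYPE_MEANS = {
    "upright":      [100, 110, 100, 100, 110, 100],
    "lean_left":    [150, 165, 150,  45,  50,  45],
    "lean_right":   [ 45,  50,  45, 150, 165, 150],
    "lean_forward": [150, 100,  45, 150, 100,  45],
    "slouch_back":  [ 45, 100, 160,  45, 100, 160],
    "edge_sit":     [160,  60,  15, 160,  60,  15],
    "empty":        [  2,   2,   2,   2,   2,   2],
}


def min_archetype_separation() -> float:
    """Smallest pairwise Euclidean distance between occupied archetype means."""
    means = [np.asarray(_ARCHETYPE_MEANS[l], float) for l in ARCHETYPE_LABELS]
    d = min(np.linalg.norm(a - b)
            for i, a in enumerate(means) for b in means[i + 1:])
    return float(d)


def default_archetypes(spread_frac: float = 0.10) -> list[PostureArchetype]:
    """The seven posture archetypes at a stated within-class spread.

    ``spread_frac`` scales the per-channel noise SD as a fraction of the
    minimum pairwise separation between archetype means (default 10%).
    """
    spread = spread_frac * min_archetype_separation()
    return [PostureArchetype(l, np.asarray(_ARCHETYPE_MEANS[l], float), spread)
            for l in ARCHETYPE_LABELS]


# ---------------------------------------------------------------------------
# BCG


def _beat_wavelet(tau: np.ndarray) -> np.ndarray:
    return np.exp(-tau ** 2 / (2 * BEAT_SIGMA_S ** 2)) * np.sin(
        2 * np.pi * BEAT_CARRIER_HZ * tau)


def gen_bcg(
    duration: float,
    hr: float | Callable[[float], float] = 60.0,
    resp_rate: float = 0.25,
    resp_amp: float = 0.5,
    noise_sd: float = 0.0,
    fs: float = 256.0,
    seed: int = 0,
) -> tuple[RawBCG, BCGGroundTruth]:
    """Synthesize a BCG series with exactly known beat times.

    ``hr`` is a constant in bpm or a callable ``bpm(t_seconds)``; beats are
    placed iteratively at the instantaneous interval 60/hr(t).  Beat
    amplitude is 1, so ``noise_sd`` is directly a fraction of the beat
    amplitude.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    hr_fn = hr if callable(hr) else (lambda t, _h=float(hr): _h)
    h0 = hr_fn(0.0)
    if not (30.0 <= h0 <= 180.0):
        raise InvalidArgumentError("heart rate must be within 30-180 bpm")

    beat_times = []
    t = 0.5 * 60.0 / h0
    while t < duration:
        beat_times.append(t)
        h = hr_fn(t)
        if not (30.0 <= h <= 180.0):
            raise InvalidArgumentError("heart rate profile left 30-180 bpm")
        t += 60.0 / h
    beat_times = np.asarray(beat_times)

    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs
    sig = np.zeros(n)
    half = BEAT_SUPPORT_S / 2
    for tb in beat_times:
        i0 = max(int(np.ceil((tb - half) * fs)), 0)
        i1 = min(int(np.floor((tb + half) * fs)) + 1, n)
        sig[i0:i1] += _beat_wavelet(tgrid[i0:i1] - tb)
    if resp_amp:
        sig += resp_amp * np.sin(2 * np.pi * resp_rate * tgrid)
    if noise_sd:
        rng = np.random.default_rng(seed)
        sig += rng.normal(0.0, noise_sd, size=n)
    truth = BCGGroundTruth(beat_times, resp_rate, noise_sd, seed)
    return RawBCG(sig, fs), truth


# ---------------------------------------------------------------------------
# IBI streams (respiratory sinus arrhythmia)


def gen_ibi_stream(
    duration: float,
    base_ibi: float = 850.0,
    rsa_depth: float = 50.0,
    breath_rate: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
) -> IBISeries:
    """Breathing-modulated IBI stream: base + RSA sinusoid + noise.

    The k-th interval is ``base_ibi + rsa_depth*sin(2*pi*breath_rate*t_k)``
    (plus Gaussian noise) evaluated at the cumulative beat time ``t_k``.
    All intervals are marked valid.
    """
    if base_ibi <= 0:
        raise InvalidArgumentError("base_ibi must be positive")
    if rsa_depth < 0 or duration <= 0:
        raise InvalidArgumentError("rsa_depth must be >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    times = [t0]
    ibis = []
    t = t0
    while t - t0 < duration:
        ibi = base_ibi + rsa_depth * np.sin(2 * np.pi * breath_rate * (t - t0))
        if noise_sd:
            ibi += rng.normal(0.0, noise_sd)
        ibi = max(ibi, 1.0)
        t += ibi / 1000.0
        times.append(t)
        ibis.append(ibi)
    # store exact diffs so the series invariant holds to the last bit
    times = np.asarray(times)
    ibis = np.diff(times) * 1000.0
    return IBISeries(times, ibis, np.ones(ibis.size, dtype=bool))


# ---------------------------------------------------------------------------
# pressure frames


def gen_pressure(
    archetype: PostureArchetype,
    n_frames: int,
    seed: int = 0,
    rate_hz: float = 10.0,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw labeled pressure frames around an archetype mean.

    Returns ``(times, frames, labels)`` with frames of shape (n, 6), clipped
    at zero.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = rng.normal(archetype.mean_pressures, archetype.spread,
                        size=(n_frames, 6))
    np.clip(frames, 0.0, None, out=frames)
    times = t0 + np.arange(n_frames) / rate_hz
    return times, frames, [archetype.label] * n_frames


def gen_pressure_dataset(
    archetypes: list[PostureArchetype] | None = None,
    n_frames: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked frames for all archetypes: returns (X of shape (n,6), labels)."""
    if archetypes is None:
        archetypes = default_archetypes()
    xs, ys = [], []
    for i, arch in enumerate(archetypes):
        _, frames, labels = gen_pressure(arch, n_frames, seed=seed * 1009 + i)
        xs.append(frames)
        ys.extend(labels)
    return np.vstack(xs), np.asarray(ys)


# ---------------------------------------------------------------------------
# session scripts


@dataclass(frozen=True)
class SessionScript:
    """A merged timeline of pressure frames and IBIs with mode ground truth.

    ``annotations`` are (t_start, t_end, expected_mode) windows; detection
    latency means the realized transitions fall inside, not exactly at, the
    window edges.
    """

    scenario: str
    frame_times: np.ndarray       # seconds, 10 Hz
    frames: np.ndarray            # (n, 6)
    frame_labels: np.ndarray
    ibis: IBISeries
    annotations: tuple
    calibration: CalibrationRange
    seed: int

    @property
    def expected_modes(self) -> tuple[str, ...]:
        """Ordered sequence of expected modes with repeats collapsed."""
        seq: list[str] = []
        for _, _, m in self.annotations:
            if not seq or seq[-1] != m:
                seq.append(m)
        return tuple(seq)


_SCRIPT_RATE_HZ = 10.0
_SCRIPT_CAL = CalibrationRange(hrv_min=15.0, hrv_max=80.0)


def _posture_segments(segments, seed):
    """segments: list of (duration_s, label). Returns times, frames, labels."""
    arch = {a.label: a for a in default_archetypes()}
    times, frames, labels = [], [], []
    t = 0.0
    for k, (dur, label) in enumerate(segments):
        n = int(round(dur * _SCRIPT_RATE_HZ))
        ts, fr, lb = gen_pressure(arch[label], n, seed=seed * 7919 + k,
                                  rate_hz=_SCRIPT_RATE_HZ, t0=t)
        times.append(ts)
        frames.append(fr)
        labels.extend(lb)
        t += dur
    return np.concatenate(times), np.vstack(frames), np.asarray(labels)


def gen_session_script(scenario: str, seed: int = 0) -> SessionScript:
    """Build a scripted closed-loop scenario with annotated expected modes.

    Scenarios:

    - ``sedentary_buildup``: 35 min of continuous upright sitting with an
      unremarkable heartbeat; the ambient intervention mapping should stay
      active throughout while brightness climbs.
    - ``stretch_break``: 2 min seated, then a left-hold / right-hold lateral
      weight-shift sequence (one full repetition), then seated again.
    - ``breathing_break``: 2 min seated with shallow RSA, then 2 min of slow
      deep breathing (0.1 Hz, deep RSA) driving the running HRV up, then
      shallow again.
    """
    if scenario == "sedentary_buildup":
        dur = 35 * 60.0
        times, frames, labels = _posture_segments([(dur, "upright")], seed)
        ibis = gen_ibi_stream(dur, base_ibi=850, rsa_depth=20,
                              breath_rate=0.25, noise_sd=10, seed=seed)
        annotations = ((0.0, dur, "intervention"),)
    elif scenario == "stretch_break":
        segs = [(120, "upright"),
                (7, "lean_left"), (2, "upright"), (7, "lean_right"),
                (44, "upright"), (120, "upright")]
        times, frames, labels = _posture_segments(segs, seed)
        dur = times[-1] + 1 / _SCRIPT_RATE_HZ
        ibis = gen_ibi_stream(dur, base_ibi=850, rsa_depth=20,
                              breath_rate=0.25, noise_sd=10, seed=seed)
        annotations = ((0.0, 120.0, "intervention"),
                       (120.0, 145.0, "stretch"),
                       (145.0, dur, "intervention"))
    elif scenario == "breathing_break":
        segs = [(120, "upright"), (120, "upright"), (60, "upright")]
        times, frames, labels = _posture_segments(segs, seed)
        dur = times[-1] + 1 / _SCRIPT_RATE_HZ
        shallow = gen_ibi_stream(120, base_ibi=850, rsa_depth=10,
                                 breath_rate=0.25, noise_sd=3, seed=seed)
        deep = gen_ibi_stream(120, base_ibi=900, rsa_depth=120,
                              breath_rate=0.1, noise_sd=3, seed=seed + 1,
                              t0=float(shallow.beat_times[-1]))
        tail = gen_ibi_stream(60, base_ibi=850, rsa_depth=10,
                              breath_rate=0.25, noise_sd=3, seed=seed + 2,
                              t0=float(deep.beat_times[-1]))
        bt = np.concatenate([shallow.beat_times, deep.beat_times[1:],
                             tail.beat_times[1:]])
        ibis_ms = np.diff(bt) * 1000.0
        ibis = IBISeries(bt, ibis_ms, np.ones(ibis_ms.size, dtype=bool))
        annotations = ((0.0, 125.0, "intervention"),
                       (125.0, 240.0, "breathing"),
                       (240.0, dur, "intervention"))
    else:
        raise InvalidArgumentError(f"unknown scenario: {scenario!r}")

    return SessionScript(scenario, times, frames, labels, ibis,
                         annotations, _SCRIPT_CAL, seed)
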