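"""Ambient-light mappings for the 28-LED strip and the session state machine.

Three display modes:

- **Intervention** (passive awareness): accumulated sitting time 10-30 min is
  mapped to brightness 10-255 and the running HRV (calibrated max -> min) to
  saturation 10-255, so a long-seated, stressed user sees a bright, saturated
  orange; a rested one sees an almost-invisible glow.
- **Stretch guidance**: a wipe cue toward the target side, hue blending blue
  to green with progress toward the lateral-shift target, a seeded sparkle on
  target, then a side switch.
- **HRV biofeedback** (slow breathing): the inter-beat interval 550-1150 ms
  is mapped to brightness 10-255 (light breathes with the user), and the
  running HRV (calibrated min -> max) to saturation 10-250, so a more
  saturated color signals improved HRV.  The two modes intentionally run the
  HRV-saturation mapping in opposite directions, and the biofeedback
  saturation ceiling is 250, not 255.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace

import numpy as np

from .bcg import CalibrationRange, HRVState, update_hrv
from .config import DEFAULT_CONFIG, Config
from .errors import CalibrationRequiredError, InvalidArgumentError
from .posture import (
    ANNModel,
    SedentaryClock,
    classify,
    detect_exercise_start,
    lateral_shift_index,
    occupancy,
    update_sedentary,
)

__all__ = [
    "LightFrame",
    "StretchSession",
    "SessionTick",
    "linmap",
    "hsb_to_rgb",
    "uniform_frame",
    "intervention_frame",
    "biofeedback_frame",
    "new_stretch_session",
    "stretch_step",
    "run_session",
]

N_LEDS = 28
PHASES = ("cue_left", "cue_right", "moving", "hold", "switch")


def linmap(x: float, src_lo: float, src_hi: float,
           dst_lo: float, dst_hi: float) -> float:
    """Affine map of ``x`` from [src_lo, src_hi] to [dst_lo, dst_hi], clamped.

    An inverted source (src_lo > src_hi) inverts the mapping direction, which
    is how the intervention mode maps *high* HRV to *low* saturation.
    """
    if src_lo == src_hi:
        raise InvalidArgumentError("source endpoints must differ")
    y = dst_lo + (x - src_lo) * (dst_hi - dst_lo) / (src_hi - src_lo)
    lo, hi = min(dst_lo, dst_hi), max(dst_lo, dst_hi)
    return float(min(max(y, lo), hi))


def hsb_to_rgb(hue: float, sat: float, bri: float) -> tuple[int, int, int]:
    """HSV -> 8-bit RGB with hue in degrees and S, V on the 0-255 scale."""
    if not (0.0 <= hue <= 360.0):
        raise InvalidArgumentError("hue must be within 0-360 degrees")
    if not (0.0 <= sat <= 255.0 and 0.0 <= bri <= 255.0):
        raise InvalidArgumentError("saturation/brightness must be within 0-255")
    r, g, b = colorsys.hsv_to_rgb((hue % 360.0) / 360.0, sat / 255.0, bri / 255.0)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


@dataclass(frozen=True)
class LightFrame:
    """One rendered strip state: 28 RGB triples plus the HSB that drove them."""

    leds: tuple                  # 28 (r, g, b) triples, 0-255 each
    hsb: tuple                   # (hue_deg, sat_0_255, bri_0_255)
    mode_tag: str

    def __post_init__(self):
        if len(self.leds) != N_LEDS:
            raise InvalidArgumentError(f"frame must have exactly {N_LEDS} LEDs")
        for led in self.leds:
            if len(led) != 3 or any(not (0 <= c <= 255) for c in led):
                raise InvalidArgumentError("LED channels must be within 0-255")

    @property
    def brightness(self) -> float:
        return self.hsb[2]

    @property
    def saturation(self) -> float:
        return self.hsb[1]


def uniform_frame(hue: float, sat: float, bri: float, mode_tag: str) -> LightFrame:
    rgb = hsb_to_rgb(hue, sat, bri)
    return LightFrame(tuple([rgb] * N_LEDS), (hue, sat, bri), mode_tag)


# ---------------------------------------------------------------------------
# intervention & biofeedback


def intervention_frame(seated_minutes: float, hrv40: float,
                       calibration: CalibrationRange | None,
                       cfg: Config = DEFAULT_CONFIG) -> LightFrame:
    """Ambient awareness frame: sitting time -> brightness, HRV -> saturation.

    Saturation runs from the calibrated *maximum* HRV (10, relaxed) to the
    *minimum* (255, stressed): lower HRV means a more saturated orange.
    """
    if calibration is None:
        raise CalibrationRequiredError("intervention mapping needs an HRV calibration")
    bri = linmap(seated_minutes, cfg.sedentary_lo_min, cfg.sedentary_hi_min,
                 cfg.brightness_lo, cfg.brightness_hi)
    sat = linmap(hrv40, calibration.hrv_max, calibration.hrv_min,
                 cfg.intervention_sat_lo, cfg.intervention_sat_hi)
    return uniform_frame(cfg.intervention_hue, sat, bri, "intervention")


def biofeedback_frame(ibi_ms: float, hrv40: float,
                      calibration: CalibrationRange | None,
                      base_hue: float | None = None,
                      cfg: Config = DEFAULT_CONFIG) -> LightFrame:
    """Breathing biofeedback frame: IBI -> brightness, HRV -> saturation.

    Brightness follows the heartbeat interval (550-1150 ms -> 10-255), so the
    light brightens on inhalation and dims on exhalation; saturation grows
    with HRV up to a ceiling of 250.
    """
    if calibration is None:
        raise CalibrationRequiredError("biofeedback mapping needs an HRV calibration")
    if base_hue is None:
        base_hue = cfg.biofeedback_hue
    bri = linmap(ibi_ms, cfg.biofeedback_ibi_lo_ms, cfg.biofeedback_ibi_hi_ms,
                 cfg.brightness_lo, cfg.brightness_hi)
    sat = linmap(hrv40, calibration.hrv_min, calibration.hrv_max,
                 cfg.biofeedback_sat_lo, cfg.biofeedback_sat_hi)
    return uniform_frame(base_hue, sat, bri, "breathing")


# ---------------------------------------------------------------------------
# stretch guidance state machine


@dataclass(frozen=True)
class StretchSession:
    """State of one guided lateral-stretch exercise.

    Phase cycle (one side): ``cue_* -> moving -> hold -> switch`` and back to
    the cue of the opposite side; ``reps_done`` increments once per completed
    left+right pair.
    """

    phase: str = "cue_left"
    target_side: str = "left"
    hold_elapsed: float = 0.0
    reps_done: int = 0
    rng_seed: int = 0
    phase_elapsed: float = 0.0
    sparkle_bri: tuple = ()
    _draws: int = 0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise InvalidArgumentError(f"unknown phase {self.phase!r}")


def new_stretch_session(seed: int = 0) -> StretchSession:
    return StretchSession(rng_seed=seed)


def _signed_progress(shift: float, target_side: str, threshold: float) -> float:
    s = shift if target_side == "left" else -shift
    return s / threshold


def _wipe_frame(session: StretchSession, cfg: Config) -> LightFrame:
    """6-LED bright segment translating across the strip toward the target."""
    pos = (session.phase_elapsed * cfg.wipe_speed_leds_s) % (N_LEDS + 6)
    if session.target_side == "left":
        start = (N_LEDS - 6) - pos    # sweep right -> left, starting on-strip
    else:
        start = pos
    bri_bg, bri_seg = 30.0, 255.0
    hue = cfg.stretch_hue_start
    leds = []
    for i in range(N_LEDS):
        lit = start <= i < start + 6
        leds.append(hsb_to_rgb(hue, 255.0, bri_seg if lit else bri_bg))
    return LightFrame(tuple(leds), (hue, 255.0, bri_seg), "stretch")


def _sparkle_frame(session: StretchSession, cfg: Config) -> tuple[StretchSession, LightFrame]:
    """Seeded per-LED brightness jitter; ~30% of LEDs re-randomized per tick."""
    rng = np.random.default_rng((session.rng_seed, session._draws))
    bri = np.asarray(session.sparkle_bri if session.sparkle_bri
                     else rng.uniform(80, 255, N_LEDS))
    redo = rng.random(N_LEDS) < 0.30
    bri = np.where(redo, rng.uniform(80, 255, N_LEDS), bri)
    hue = cfg.stretch_hue_target
    leds = tuple(hsb_to_rgb(hue, 255.0, float(b)) for b in bri)
    session = replace(session, sparkle_bri=tuple(float(b) for b in bri),
                      _draws=session._draws + 1)
    return session, LightFrame(leds, (hue, 255.0, float(bri.mean())), "stretch")


def stretch_step(session: StretchSession, lateral_shift: float,
                 dt: float, cfg: Config = DEFAULT_CONFIG
                 ) -> tuple[StretchSession, LightFrame]:
    """Advance the stretch state machine by ``dt`` and render its frame.

    ``lateral_shift`` is the signed weight-shift index in [-1, 1] (positive =
    left).  Cue phases show a wipe toward the target side; once the user
    starts moving the hue blends blue -> green with progress; at the target
    a sparkle plays for the hold duration; then the side flips and the hue
    resets to blue.
    """
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if not -1.0 <= lateral_shift <= 1.0:
        raise InvalidArgumentError("lateral_shift must be within [-1, 1]")
    thr = cfg.lateral_shift_threshold
    p = _signed_progress(lateral_shift, session.target_side, thr)

    if session.phase in ("cue_left", "cue_right"):
        session = replace(session, phase_elapsed=session.phase_elapsed + dt)
        if p >= 0.15:
            session = replace(session, phase="moving", phase_elapsed=0.0)
        else:
            return session, _wipe_frame(session, cfg)

    if session.phase == "moving":
        if p >= 1.0:
            session = replace(session, phase="hold", hold_elapsed=0.0,
                              sparkle_bri=())
        else:
            frac = min(max(p, 0.0), 1.0)
            hue = cfg.stretch_hue_start + frac * (cfg.stretch_hue_target
                                                  - cfg.stretch_hue_start)
            return session, uniform_frame(hue, 255.0, 255.0, "stretch")

    if session.phase == "hold":
        session = replace(session, hold_elapsed=session.hold_elapsed + dt)
        if p < 1.0 and session.hold_elapsed < cfg.hold_duration_s:
            session = replace(session, phase="moving", hold_elapsed=0.0)
            frac = min(max(p, 0.0), 1.0)
            hue = cfg.stretch_hue_start + frac * (cfg.stretch_hue_target
                                                  - cfg.stretch_hue_start)
            return session, uniform_frame(hue, 255.0, 255.0, "stretch")
        if session.hold_elapsed >= cfg.hold_duration_s:
            done_side = session.target_side
            new_side = "right" if done_side == "left" else "left"
            session = replace(session, phase="switch", target_side=new_side,
                              hold_elapsed=0.0, phase_elapsed=0.0,
                              reps_done=session.reps_done
                              + (1 if done_side == "right" else 0))
            return session, uniform_frame(cfg.stretch_hue_start, 255.0, 255.0,
                                          "stretch")
        return _sparkle_frame(session, cfg)

    # switch: one transitional tick, then cue the new side
    session = replace(session, phase=f"cue_{session.target_side}",
                      phase_elapsed=0.0)
    return session, _wipe_frame(session, cfg)


# ---------------------------------------------------------------------------
# closed-loop session simulation


@dataclass(frozen=True)
class SessionTick:
    t: float
    mode: str
    frame: LightFrame
    seated_minutes: float
    hrv40: float
    posture: str


def run_session(script, model: ANNModel,
                calibration: CalibrationRange | None = None,
                cfg: Config = DEFAULT_CONFIG,
                reps_target: int = 1,
                breathing_duration_s: float = 60.0,
                stretch_timeout_s: float = 180.0,
                cooldown_s: float = 60.0) -> list[SessionTick]:
    """Replay a scripted scenario through the full closed loop.

    Per pressure frame (10 Hz): update occupancy and the sedentary clock,
    classify posture, advance the HRV estimator with any heartbeats that
    occurred, check (once per second) whether a microbreak exercise started,
    and render the active mode's frame.  A completed exercise resets the
    sedentary clock, so the display returns to its near-invisible resting
    state; detection re-arms only after ``cooldown_s`` so one scripted
    exercise bout is not counted twice.
    """
    if calibration is None:
        calibration = script.calibration
    clock = SedentaryClock()
    hrv_state = HRVState(window=cfg.hrv_window_beats)
    hrv_t: list[float] = []
    hrv_v: list[float] = []
    beat_i = 0
    last_ibi = float(np.mean(script.ibis.ibis_ms)) if len(script.ibis) else 850.0
    mode = "intervention"
    stretch: StretchSession | None = None
    mode_entered_t = 0.0
    last_completed_t = -np.inf
    ticks: list[SessionTick] = []
    times = script.frame_times
    idx_all = lateral_shift_index(script.frames)

    for i, t in enumerate(times):
        dt = float(times[i] - times[i - 1]) if i else float(times[1] - times[0])
        x = script.frames[i]
        occ = occupancy(x, cfg.occupancy_threshold)
        # consume heartbeats up to t
        while beat_i < len(script.ibis) and script.ibis.beat_times[beat_i + 1] <= t:
            if script.ibis.valid[beat_i]:
                last_ibi = float(script.ibis.ibis_ms[beat_i])
                hrv_state = update_hrv(hrv_state, last_ibi)
                if hrv_state.warmed_up:
                    # warm-up values climb from the zero seed and would look
                    # like a breathing-induced HRV rise to the detector
                    hrv_t.append(float(script.ibis.beat_times[beat_i + 1]))
                    hrv_v.append(hrv_state.hrv40)
            beat_i += 1
        label, _ = classify(model, x)
        exercise_completed = False

        if mode == "intervention":
            if (i % 10 == 0 and t - times[0] >= 10.0
                    and t - last_completed_t >= cooldown_s):
                w = times >= t - 10.0
                w &= times <= t
                try:
                    started = detect_exercise_start(
                        times[w], script.frames[w],
                        np.asarray(hrv_t), np.asarray(hrv_v),
                        calibration, cfg)
                except CalibrationRequiredError:
                    started = "none"
                if started == "stretch":
                    mode = "stretch"
                    stretch = new_stretch_session(seed=script.seed)
                    mode_entered_t = t
                elif started == "breathing":
                    mode = "breathing"
                    mode_entered_t = t

        if mode == "stretch":
            assert stretch is not None
            stretch, frame = stretch_step(stretch, float(idx_all[i]), dt, cfg)
            if stretch.reps_done >= reps_target or t - mode_entered_t > stretch_timeout_s:
                exercise_completed = True
                last_completed_t = t
                mode = "intervention"
                stretch = None
        elif mode == "breathing":
            frame = biofeedback_frame(last_ibi, hrv_state.hrv40, calibration,
                                      cfg=cfg)
            if t - mode_entered_t >= breathing_duration_s:
                exercise_completed = True
                last_completed_t = t
                mode = "intervention"

        clock = update_sedentary(clock, occ, dt, exercise_completed, t=t)

        if mode == "intervention":
            frame = intervention_frame(clock.seated_minutes, hrv_state.hrv40,
                                       calibration, cfg)
        ticks.append(SessionTick(float(t), frame.mode_tag if mode != "intervention"
                                 else "intervention", frame,
                                 clock.seated_minutes, hrv_state.hrv40, label))
    return ticks
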