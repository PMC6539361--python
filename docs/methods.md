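# Methods

This note documents the models, algorithms and design choices behind
`sitlight`, what the synthetic data does and does not emulate, and the
numerical conventions that matter for reproducing its outputs.

## BCG processing

**Signal model.** A seated person's ballistocardiogram is treated as a
train of band-limited oscillatory bursts — one per heartbeat — superimposed
on low-frequency respiratory drift and broadband noise. The pipeline makes
no use of beat morphology beyond "a burst of energy in a known band".

**Wavelet band selection.** Denoising keeps only the level-4 detail band of
a Haar wavelet decomposition. At the default sampling rate of 256 Hz this
band spans fs/32–fs/16 = 8–16 Hz, bracketing the burst oscillation while
rejecting respiration (~0.1–0.5 Hz) and most high-frequency noise. The
band is reconstructed with the **undecimated (stationary) transform**
rather than a decimated DWT. This is deliberate: a decimated level-4 Haar
detail is piecewise constant on 2⁴-sample blocks, so the reconstructed
burst — and therefore the detected beat time — snaps to the dyadic grid in
~62 ms quanta depending on where the beat falls relative to that grid.
Measured on synthetic signals, that quantisation alone puts a ~25 ms floor
under the mean absolute IBI error; the shift-invariant reconstruction of
the same band removes it entirely. Signals are edge-padded to a multiple of
2⁴ and trimmed after the inverse transform, so output length equals input
length, and the five band reconstructions (a4, d4–d1) sum to the input to
machine precision.

**Envelope.** The beat locations are emphasised by a moving mean absolute
deviation: `out[k] = mean(|x_j − mean(window)|)` over a centred window,
truncated (not padded) at the series edges; for an even sample count the
window extends one extra sample to the left of the centre. The default
window is **150 ms, matched to the beat-complex support**. A window much
longer than the burst produces a flat-topped envelope (the MAD is constant
while the burst sits fully inside the window), and the subsequent argmax
then wanders across the plateau under noise; with a 300 ms window the IBI
error grows by an order of magnitude. The window is a config parameter
(`mad_window_ms`).

**Beat picking.** A sample is a beat iff it is the maximum of every 400 ms
window containing it (equivalently, of its ±400 ms neighbourhood). Ties
break to the earliest sample and a refractory gap of one full window is
enforced, so no two beats are closer than 400 ms; this limits detectable
heart rate to 150 bpm, comfortably above sedentary office conditions. A
flat envelope yields no beats.

**IBI validity gate.** An interval is valid when it lies in 300–1500 ms
(heart rate 40–200 bpm) *and* within ±30% of the previous valid interval;
the first in-range interval is accepted unconditionally. The relative-jump
clause rejects the halved/doubled intervals produced by a missed or
spurious beat.

**Recursive HRV.** Per valid beat,

    HRV40' = (39·HRV40 + |IBI − IBI40|) / 40     (pre-update IBI40)
    IBI40' = (39·IBI40 + IBI) / 40

with the deviation update applied first, using the pre-update running mean;
the opposite order is a one-line change and is documented here because the
two differ in the twelfth decimal after one step and measurably after many.
The recursion is an exponentially weighted mean absolute deviation with an
effective 40-beat window — *not* a windowed SDNN: on i.i.d. normal IBIs it
converges to σ·√(2/π), about 80% of the SDNN. The state is seeded with the
first valid IBI (deviation 0) and flagged as warm-up until 40 valid beats
have been consumed; consumers that look for HRV *trends* (the breathing
detector) must ignore warm-up values, whose climb from zero mimics a
genuine HRV rise.

**Calibration.** `hrv_max` is the SDNN (population, divide-by-n) of ≥60 s
of relaxed slow breathing; `hrv_min` the SDNN of the minute following
physical exercise. An inverted range raises a calibration-failure error
rather than being silently swapped, since it indicates a botched protocol
run.

## Posture classification

The network is intentionally small: 6 pressure inputs normalised by
per-channel training maxima (stored with the model, giving a per-user
weight-shift range hook), a sigmoid hidden layer (default 10 units), a
softmax output over the class set, and biases throughout. Training
minimises the sum-of-squares error against one-hot targets — Levenberg–
Marquardt needs residuals, which rules out cross-entropy — with the full
analytic Jacobian. LM specifics: λ₀ = 10⁻³, ×10 on a rejected step, ÷10 on
an accepted one, at most 200 iterations, stop when the relative loss drop
falls below 10⁻⁸ or no descent direction exists at maximal damping; the
accepted-loss trace is stored with the model and is non-increasing by
construction. Weights initialise uniform(−0.5, 0.5) from a seed. With
identity activations and a linear output the same trainer reproduces the
closed-form least-squares solution, which the tests exploit as an
optimality oracle.

The seven posture archetypes (upright, lean left/right/forward, slouch
back, edge sit, empty) are an artifact choice: the pad layout has a left
and a right triplet of sensors (front/middle/rear), and the archetype means
are hand-designed on that geometry with a minimum pairwise separation of
~72 sensor units. The stated within-class spread is 10% of that minimum
separation. Occupancy is a simple total-load threshold at 20% of the
upright archetype's total.

**Sedentary clock.** Accumulates seated minutes while occupied; a gap
shorter than 60 s pauses accumulation, a continuous minute away or a
completed exercise session resets it. The clock can never exceed elapsed
time.

**Microbreak detection.** Stretch: the signed lateral imbalance
(L−R)/(L+R) stays beyond 0.35 for 2 s. Breathing: posture stable (small
imbalance, steady total load) while the warmed-up HRV40 rises by more than
10% of the calibrated range per 30 s. Stretch wins when both fire; a
breathing candidate without a calibration raises an error instead of
guessing a range.

## Light mappings

All mappings are clamped affine maps (`linmap`), including inverted-source
forms. Printed constants: intervention maps 10–30 min seated to brightness
10–255 and HRV max→min to saturation 10–255 at hue 30° (orange);
biofeedback maps IBI 550–1150 ms to brightness 10–255 and HRV min→max to
saturation 10–**250**. The asymmetric saturation ceiling (250 vs 255) is
preserved deliberately, and the two modes run the HRV→saturation map in
opposite directions by design: in intervention, saturated = stressed; in
biofeedback, saturated = improving.

Stretch guidance is a five-phase machine (cue_left/cue_right → moving →
hold → switch): cues render a 6-LED wipe travelling at 14 LED/s toward the
target side in blue (240°); moving blends hue linearly toward green (120°)
with progress = shift/threshold; at the target a seeded sparkle
(per-LED brightness jitter, ~30% of LEDs re-randomised per tick) plays for
the 3 s hold; switch flips the side, resets blue, and increments the rep
count once per completed left+right pair. Sparkle randomness derives from
(session seed, draw counter), so identical call sequences render identical
frames. HSV→RGB uses the standard conversion with S and V rescaled from
0–255.

The closed-loop simulator replays a scripted scenario at the script's
10 Hz frame rate: update occupancy and the sedentary clock, classify
posture, advance HRV with any elapsed heartbeats, check for exercise onset
once per second, render the active mode. A completed exercise resets the
clock (the display returns to its brightness-10 resting state) and starts
a 60 s detection cooldown so one scripted bout is not counted twice.

## Synthetic data: what it does and does not show

The BCG generator places beats iteratively at the instantaneous 60/HR
spacing and adds, per beat, a Gaussian-windowed 15 Hz sinusoid with 150 ms
support (amplitude 1), plus a respiratory sine (default 0.25 Hz, amplitude
0.5) and white Gaussian noise; `noise_sd` is therefore directly a fraction
of beat amplitude. IBI streams embed respiratory sinus arrhythmia as a
sinusoid in the interval sequence. Pressure frames are archetype means
plus clipped Gaussian noise. Everything is a pure function of its
arguments including the seed.

Passing tests on this data show that the *algorithms* recover what was
embedded — exact beat times, class labels, breathing rate, scripted mode
transitions — under controlled noise. They do not show robustness to what
the generator omits: realistic I/J/K-wave BCG morphology, motion artifacts,
non-stationary noise, posture transitions between archetypes, or real
inter-subject variability. The reference accuracy figure used as the
pipeline's acceptance bound (mean absolute IBI error ≤ 5.77 ms) is checked
under the stated synthetic conditions (fs = 256 Hz, HR 50–100 bpm, 120 s
runs, 10% noise, 5 seeds — ~2800 intervals, which runs in seconds on one
CPU), not on human recordings.

## Known limitations

- The sampling rate is a free parameter; the 8–16 Hz detail band only
  brackets the burst carrier at fs ≈ 256 Hz. Other rates need a different
  level or carrier.
- No frequency-domain HRV, respiration-rate estimation, or multi-channel
  sensor fusion.
- The posture network is trained per archetype set; no continual or
  transfer learning.
- The light renderer is a pure data structure; driving physical LEDs,
  gamma/color calibration, and GUI visualisation are out of scope.
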