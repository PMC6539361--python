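"""Sitting-posture classification and sedentary/exercise-state tracking.

A three-layer feedforward network maps the six seat-pad pressure channels to
posture-class probabilities.  The hidden layer computes
``H = sigma(W^T x + b_h)`` and the output ``softmax(W2^T H + b_o)``; training
minimises the sum-of-squares error against one-hot targets with the
Levenberg-Marquardt algorithm (damped Gauss-Newton on the full residual
Jacobian with multiplicative lambda adaptation), the standard trainer for
small pressure-sensor posture networks.

The module also owns the occupancy test, the sedentary clock that feeds the
ambient intervention, and the detector that decides when a user has started
a stretch (sustained lateral weight shift) or slow-breathing (still posture
with rapidly rising HRV) microbreak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bcg import CalibrationRange
from .config import DEFAULT_CONFIG, Config
from .errors import (
    CalibrationRequiredError,
    InvalidArgumentError,
    InvalidModelError,
    TrainingFailedError,
)

__all__ = [
    "ANNModel",
    "SedentaryClock",
    "forward",
    "classify",
    "train_lm",
    "lm_optimize",
    "occupancy",
    "update_sedentary",
    "lateral_shift_index",
    "detect_exercise_start",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ANNModel:
    """Weights of the three-layer feedforward posture classifier.

    ``norm`` holds the per-channel calibration maxima; inputs are divided by
    it before the first layer so the network sees the user's own
    weight-shift range on a common scale.
    """

    W: np.ndarray                  # (6, n_hidden)
    b_h: np.ndarray                # (n_hidden,)
    W2: np.ndarray                 # (n_hidden, n_classes)
    b_o: np.ndarray                # (n_classes,)
    class_labels: tuple
    norm: np.ndarray               # (6,), per-channel input scale
    hidden_activation: str = "sigmoid"
    output_activation: str = "softmax"
    loss_trace: tuple = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("W", "b_h", "W2", "b_o", "norm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n_in, n_hid = self.W.shape
        n_out = self.W2.shape[1]
        if (self.b_h.shape != (n_hid,) or self.W2.shape != (n_hid, n_out)
                or self.b_o.shape != (n_out,) or self.norm.shape != (n_in,)):
            raise InvalidModelError("inconsistent weight dimensions")
        if len(self.class_labels) != n_out:
            raise InvalidModelError("class_labels must match output width")
        if not all(np.all(np.isfinite(a)) for a in
                   (self.W, self.b_h, self.W2, self.b_o)):
            raise InvalidModelError("weights must be finite")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W": self.W.tolist(), "b_h": self.b_h.tolist(),
            "W2": self.W2.tolist(), "b_o": self.b_o.tolist(),
            "class_labels": list(self.class_labels),
            "norm": self.norm.tolist(),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "loss_trace": list(self.loss_trace),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ANNModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["W"]), np.asarray(d["b_h"]),
                   np.asarray(d["W2"]), np.asarray(d["b_o"]),
                   tuple(d["class_labels"]), np.asarray(d["norm"]),
                   d["hidden_activation"], d["output_activation"],
                   tuple(d["loss_trace"]), d["seed"])


def _forward_batch(model: ANNModel, X: np.ndarray):
    Xn = X / model.norm
    Z = Xn @ model.W + model.b_h
    H = _sigmoid(Z) if model.hidden_activation == "sigmoid" else Z
    O = H @ model.W2 + model.b_o
    Y = _softmax(O) if model.output_activation == "softmax" else O
    return Xn, H, Y


def forward(model: ANNModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector for one 6-channel pressure frame."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.W.shape[0],):
        raise InvalidModelError(
            f"frame has shape {x.shape}, model expects ({model.W.shape[0]},)")
    return _forward_batch(model, x[None, :])[2][0]


def classify(model: ANNModel, x: np.ndarray) -> tuple[str, float]:
    """Argmax class and its probability; ties broken by class order."""
    p = forward(model, x)
    i = int(np.argmax(p))
    return model.class_labels[i], float(p[i])


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


def lm_optimize(
    residual_fn,
    jacobian_fn,
    theta0: np.ndarray,
    max_iter: int = 200,
    lam0: float = 1e-3,
    lam_max: float = 1e10,
    tol: float = 1e-8,
) -> tuple[np.ndarray, list[float]]:
    """Levenberg-Marquardt minimisation of ``sum(residual**2)``.

    Damped Gauss-Newton: each step solves ``(J^T J + lam*I) d = -J^T r``;
    lambda is divided by 10 on an accepted step and multiplied by 10 on a
    rejected one.  Returns the parameters and the accepted-loss trace (which
    is non-increasing by construction).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    r = residual_fn(theta)
    loss = float(r @ r)
    trace = [loss]
    lam = lam0
    for _ in range(max_iter):
        J = jacobian_fn(theta)
        g = J.T @ r
        A = J.T @ J
        eye = np.eye(A.shape[0])
        accepted = False
        while lam <= lam_max:
            try:
                step = np.linalg.solve(A + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + step
            rc = residual_fn(cand)
            lc = float(rc @ rc)
            if np.isfinite(lc) and lc < loss:
                theta, r = cand, rc
                rel = (loss - lc) / max(loss, 1e-300)
                loss = lc
                trace.append(loss)
                lam = max(lam / 10.0, 1e-15)
                accepted = True
                if rel < tol:
                    return theta, trace
                break
            lam *= 10.0
        if not accepted:
            if not np.isfinite(loss):
                raise TrainingFailedError("loss diverged")
            # no descent direction at maximal damping: converged
            return theta, trace
    return theta, trace


def train_lm(
    X: np.ndarray,
    labels,
    n_hidden: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    lam0: float = 1e-3,
    tol: float = 1e-8,
    hidden_activation: str = "sigmoid",
    output_activation: str = "softmax",
) -> ANNModel:
    """Train the posture network on labeled frames with Levenberg-Marquardt.

    The objective is the sum-of-squares error between the network output and
    one-hot targets (LM needs residuals, not cross-entropy).  Weights are
    initialised uniform(-0.5, 0.5) from ``seed``; inputs are normalised by
    per-channel training maxima stored with the model.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("X must be (n_samples, n_channels)")
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise InvalidArgumentError("need at least 2 classes to train")
    n, n_in = X.shape
    k = len(classes)
    T = np.zeros((n, k))
    T[np.arange(n), [classes.index(l) for l in labels]] = 1.0

    norm = np.maximum(X.max(axis=0), 1e-9)
    Xn = X / norm

    rng = np.random.default_rng(seed)
    sizes = [n_in * n_hidden, n_hidden, n_hidden * k, k]
    theta0 = rng.uniform(-0.5, 0.5, size=sum(sizes))

    def unpack(theta):
        i = 0
        W = theta[i:i + sizes[0]].reshape(n_in, n_hidden); i += sizes[0]
        b_h = theta[i:i + sizes[1]]; i += sizes[1]
        W2 = theta[i:i + sizes[2]].reshape(n_hidden, k); i += sizes[2]
        b_o = theta[i:i + sizes[3]]
        return W, b_h, W2, b_o

    def fwd(theta):
        W, b_h, W2, b_o = unpack(theta)
        Z = Xn @ W + b_h
        H = _sigmoid(Z) if hidden_activation == "sigmoid" else Z
        O = H @ W2 + b_o
        Y = _softmax(O) if output_activation == "softmax" else O
        return H, Y, W2

    def residual(theta):
        _, Y, _ = fwd(theta)
        return (Y - T).ravel()

    def jacobian(theta):
        H, Y, W2 = fwd(theta)
        if output_activation == "softmax":
            # S[n,k,m] = dY_nk/dO_nm = Y_nk (delta_km - Y_nm)
            S = -Y[:, :, None] * Y[:, None, :]
            S[:, np.arange(k), np.arange(k)] += Y
        else:
            S = np.broadcast_to(np.eye(k), (n, k, k)).copy()
        if hidden_activation == "sigmoid":
            Hp = H * (1.0 - H)
        else:
            Hp = np.ones_like(H)
        # A[n,k,j] = sum_m S[n,k,m] W2[j,m] * Hp[n,j]
        A = np.einsum("nkm,jm->nkj", S, W2) * Hp[:, None, :]
        JW = np.einsum("nkj,ni->nkij", A, Xn).reshape(n * k, n_in * n_hidden)
        Jbh = A.reshape(n * k, n_hidden)
        JW2 = np.einsum("nkm,nj->nkjm", S, H).reshape(n * k, n_hidden * k)
        Jbo = S.reshape(n * k, k)
        return np.hstack([JW, Jbh, JW2, Jbo])

    theta, trace = lm_optimize(residual, jacobian, theta0,
                               max_iter=max_iter, lam0=lam0, tol=tol)
    W, b_h, W2, b_o = unpack(theta)
    return ANNModel(W, b_h, W2, b_o, classes, norm,
                    hidden_activation, output_activation,
                    tuple(trace), seed)


# ---------------------------------------------------------------------------
# occupancy and the sedentary clock


def occupancy(x: np.ndarray, threshold: float | None = None) -> bool:
    """Seat occupied iff total pressure reaches the threshold."""
    if threshold is None:
        threshold = DEFAULT_CONFIG.occupancy_threshold
    return bool(np.asarray(x, dtype=float).sum() >= threshold)


@dataclass(frozen=True)
class SedentaryClock:
    """Accumulated continuous sitting time.

    Short standing gaps (< 60 s) pause the accumulation; a continuous minute
    away from the seat, or a completed exercise session, resets it.
    """

    seated_minutes: float = 0.0
    unoccupied_s: float = 0.0
    last_break_t: float = 0.0
    reset_gap_s: float = 60.0


def update_sedentary(clock: SedentaryClock, occupied: bool, dt: float,
                     exercise_completed: bool = False,
                     t: float | None = None) -> SedentaryClock:
    """Advance the sedentary clock by one tick of ``dt`` seconds."""
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if exercise_completed:
        return replace(clock, seated_minutes=0.0, unoccupied_s=0.0,
                       last_break_t=t if t is not None else clock.last_break_t)
    if occupied:
        return replace(clock, seated_minutes=clock.seated_minutes + dt / 60.0,
                       unoccupied_s=0.0)
    gap = clock.unoccupied_s + dt
    if gap >= clock.reset_gap_s:
        return replace(clock, seated_minutes=0.0, unoccupied_s=gap,
                       last_break_t=t if t is not None else clock.last_break_t)
    return replace(clock, unoccupied_s=gap)


# ---------------------------------------------------------------------------
# microbreak-start detection


def lateral_shift_index(frames: np.ndarray) -> np.ndarray:
    """Signed left/right load imbalance, (L-R)/(L+R) in [-1, 1], per frame.

    Positive values mean weight shifted to the left triplet (channels 1-3).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    left = frames[:, :3].sum(axis=1)
    right = frames[:, 3:].sum(axis=1)
    total = left + right
    out = np.zeros(total.shape)
    nz = total > 0
    out[nz] = (left[nz] - right[nz]) / total[nz]
    return out


def detect_exercise_start(
    frame_times: np.ndarray,
    frames: np.ndarray,
    hrv_times: np.ndarray,
    hrv_values: np.ndarray,
    calibration: CalibrationRange | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> str:
    """Decide whether a stretch or breathing microbreak has just started.

    - ``stretch``: the lateral weight-shift index exceeds the threshold
      continuously for the trailing 2 s.
    - ``breathing``: the posture is stable (index well inside the threshold,
      steady total load) while the running HRV has risen over the trailing
      30 s by more than ``breathing_slope_fraction`` of the calibrated range.

    Stretch takes precedence when both fire.  Raises
    ``CalibrationRequiredError`` when a breathing candidate is seen but no
    calibration range is available.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frame_times.size < 2 or frame_times[-1] - frame_times[0] < 5.0:
        raise InvalidArgumentError("need at least 5 s of pressure frames")

    idx = lateral_shift_index(frames)
    t_end = frame_times[-1]
    recent = frame_times >= t_end - 2.0
    if recent.sum() >= 2 and np.all(np.abs(idx[recent]) > cfg.lateral_shift_threshold):
        return "stretch"

    # breathing: still posture + rapidly rising HRV
    stable_win = frame_times >= t_end - 5.0
    totals = frames[stable_win].sum(axis=1)
    stable = (np.all(np.abs(idx[stable_win]) < 0.5 * cfg.lateral_shift_threshold)
              and totals.mean() > 0
              and totals.std() / totals.mean() < 0.15)
    hrv_times = np.asarray(hrv_times, dtype=float)
    hrv_values = np.asarray(hrv_values, dtype=float)
    win = hrv_times >= t_end - 30.0
    if stable and win.sum() >= 4 and hrv_times[win][-1] - hrv_times[win][0] >= 20.0:
        tt, vv = hrv_times[win], hrv_values[win]
        slope = np.polyfit(tt - tt[0], vv, 1)[0]          # ms per second
        rise_per_30s = slope * 30.0
        if calibration is None:
            if rise_per_30s > 1e-9:
                raise CalibrationRequiredError(
                    "breathing detection needs a per-user HRV calibration")
        elif rise_per_30s > cfg.breathing_slope_fraction * (
                calibration.hrv_max - calibration.hrv_min):
            return "breathing"
    return "none"
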