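"""CSV / JSON / JSON-lines exchange formats.

All signal exchange is plain CSV at desk scale: BCG as ``time_s,value``,
pressure frames as ``time_s,f1..f6[,label]``, IBI series as
``beat_time_s,ibi_ms,valid`` and beat ground truth as ``beat_time_s``.
Calibration is a small JSON object; rendered light timelines are JSON-lines,
one object per tick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bcg import CalibrationRange, IBISeries, RawBCG
from .errors import ParseError, ValidationError

__all__ = [
    "BCG_SCHEMA", "BEAT_SCHEMA", "IBI_SCHEMA", "PRESSURE_SCHEMA",
    "read_timeseries", "write_timeseries",
    "read_bcg", "write_bcg",
    "read_ibis", "write_ibis", "write_beat_times",
    "read_pressure", "write_pressure",
    "read_calibration", "write_calibration",
    "write_timeline",
]

BCG_SCHEMA = ("time_s", "value")
BEAT_SCHEMA = ("beat_time_s",)
IBI_SCHEMA = ("beat_time_s", "ibi_ms", "valid")
PRESSURE_SCHEMA = ("time_s", "f1", "f2", "f3", "f4", "f5", "f6")

_FLOAT_FMT = "%.9g"


def read_timeseries(path: str | Path, schema: tuple,
                    time_col: str | None = None,
                    optional: tuple = (),
                    allow_nan: tuple = ()) -> pd.DataFrame:
    """Read a CSV, enforcing header schema and a strictly increasing time column.

    Columns listed in ``allow_nan`` may contain empty cells (e.g. the first
    row of an IBI file, whose opening beat has no interval).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV: {e}") from e
    for col in schema:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in schema and c not in optional]
    if extra:
        raise ParseError(f"{path}: unexpected columns {extra}")
    numeric = [c for c in schema if c != "valid"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric value in {col!r} at line {line}")
        if col not in allow_nan and df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in {col!r} at line {line}")
        df[col] = vals
    tcol = time_col or schema[0]
    t = df[tcol].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        k = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValidationError(f"{path}: time column {tcol!r} not strictly "
                              f"increasing at line {k}")
    return df


def write_timeseries(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- concrete formats -------------------------------------------------------

def write_bcg(path: str | Path, raw: RawBCG) -> None:
    write_timeseries(path, pd.DataFrame({"time_s": raw.times,
                                         "value": raw.values}))


def read_bcg(path: str | Path, fs: float | None = None) -> RawBCG:
    """Read a BCG CSV; fs is inferred from the time column unless given."""
    df = read_timeseries(path, BCG_SCHEMA)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return RawBCG(df["value"].to_numpy(), fs)


def write_beat_times(path: str | Path, beat_times: np.ndarray) -> None:
    write_timeseries(path, pd.DataFrame({"beat_time_s": np.asarray(beat_times)}))


def write_ibis(path: str | Path, ibis: IBISeries) -> None:
    # the first beat opens the series and has no interval of its own
    n = ibis.beat_times.size
    df = pd.DataFrame({
        "beat_time_s": ibis.beat_times,
        "ibi_ms": np.concatenate([[np.nan], ibis.ibis_ms]) if n else [],
        "valid": np.concatenate([[False], ibis.valid]).astype(int) if n else [],
    })
    write_timeseries(path, df)


def read_ibis(path: str | Path) -> IBISeries:
    df = read_timeseries(path, IBI_SCHEMA, allow_nan=("ibi_ms",))
    bt = df["beat_time_s"].to_numpy()
    if bt.size == 0:
        return IBISeries.empty()
    return IBISeries(bt, df["ibi_ms"].to_numpy()[1:],
                     df["valid"].to_numpy()[1:].astype(bool))


def write_pressure(path: str | Path, times: np.ndarray, frames: np.ndarray,
                   labels=None) -> None:
    data = {"time_s": times}
    for j in range(6):
        data[f"f{j+1}"] = np.asarray(frames)[:, j]
    if labels is not None:
        data["label"] = labels
    write_timeseries(path, pd.DataFrame(data))


def read_pressure(path: str | Path):
    """Returns (times, frames (n,6), labels-or-None)."""
    df = read_timeseries(path, PRESSURE_SCHEMA, optional=("label",))
    frames = df[[f"f{j+1}" for j in range(6)]].to_numpy(dtype=float)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return df["time_s"].to_numpy(), frames, labels


def write_calibration(path: str | Path, cal: CalibrationRange) -> None:
    Path(path).write_text(json.dumps(
        {"hrv_min_ms": cal.hrv_min, "hrv_max_ms": cal.hrv_max}) + "\n")


def read_calibration(path: str | Path) -> CalibrationRange:
    try:
        d = json.loads(Path(path).read_text())
        return CalibrationRange(hrv_min=float(d["hrv_min_ms"]),
                                hrv_max=float(d["hrv_max_ms"]))
    except (KeyError, ValueError, json.JSONDecodeError) as e:
        raise ParseError(f"{path}: invalid calibration file: {e}") from e


def write_timeline(path: str | Path, ticks) -> None:
    """Rendered session as JSON-lines: one {t, mode, hue, sat, bri, leds} per tick."""
    with open(path, "w") as fh:
        for tick in ticks:
            hue, sat, bri = tick.frame.hsb
            fh.write(json.dumps({
                "t": round(tick.t, 6), "mode": tick.mode,
                "hue": round(hue, 3), "sat": round(sat, 3),
                "bri": round(bri, 3),
                "leds": [list(led) for led in tick.frame.leds],
            }) + "\n")
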