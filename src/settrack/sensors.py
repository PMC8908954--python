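"""Raw collar streams to derived signals: VeDBA, heading, sett occupancy.

The collar records tri-axial acceleration and magnetometry at 40 Hz and
temperature at 7 Hz.  Acceleration is split into a *static* (gravity,
posture) and a *dynamic* (movement) component with a centred running mean;
the vector magnitude of the dynamic component is VeDBA, the speed proxy used
for dead-reckoning.  Pitch and roll estimated from the static component
de-tilt the magnetometer to give a compass heading.  Sustained dampening of
VeDBA, corroborated by the temperature rise inside the sett, marks
below-ground bouts.

Axis convention (stated explicitly because collar mountings vary): x
forward, y left, z up.  A level, north-facing body sees the horizontal
magnetic field along +x; heading is ``atan2(-m_y, m_x)`` of the de-tilted
field, clockwise from north in [0, 360).  Pitch is positive nose-up
(gravity reaction tips toward +x), roll positive when the y-axis drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "DerivedSignals",
    "ActivityBout",
    "split_static_dynamic",
    "compute_vedba",
    "compute_pitch_roll",
    "compute_heading",
    "derive_signals",
    "detect_sett_occupancy",
]

SENSOR_CSV_COLUMNS = [
    "time_s", "ax_g", "ay_g", "az_g", "mx", "my", "mz", "temp_c", "temp_valid",
]


@dataclass
class SensorStream:
    """Synchronised collar channels on a uniform sample grid.

    Temperature is carried sample-and-hold on the 40 Hz grid; ``temp_valid``
    flags the native-rate (7 Hz) samples.
    """

    t: np.ndarray                 # seconds, uniform, strictly increasing
    acc: np.ndarray               # (n, 3) in g
    mag: np.ndarray               # (n, 3) arbitrary field units
    temp: np.ndarray              # (n,) deg C, sample-and-hold
    temp_valid: np.ndarray        # (n,) bool, native temperature samples
    rate_hz: float = 40.0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("acc", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        if self.temp.shape != (n,) or self.temp_valid.shape != (n,):
            raise ValueError("temperature channels must match timestamp length")
        if self.rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate_hz, rtol=0, atol=1e-6 / self.rate_hz):
                raise ValueError("timestamps must be uniform at the stated rate")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t,
            "ax_g": self.acc[:, 0], "ay_g": self.acc[:, 1], "az_g": self.acc[:, 2],
            "mx": self.mag[:, 0], "my": self.mag[:, 1], "mz": self.mag[:, 2],
            "temp_c": self.temp,
            "temp_valid": self.temp_valid.astype(int),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path, rate_hz: Optional[float] = None) -> "SensorStream":
        df = pd.read_csv(path)
        missing = [c for c in SENSOR_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sensor CSV missing columns: {missing}")
        t = df["time_s"].to_numpy(float)
        if rate_hz is None:
            if len(t) < 2:
                raise ValueError("cannot infer sample rate from a single row")
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t=t,
            acc=df[["ax_g", "ay_g", "az_g"]].to_numpy(float),
            mag=df[["mx", "my", "mz"]].to_numpy(float),
            temp=df["temp_c"].to_numpy(float),
            temp_valid=df["temp_valid"].to_numpy(bool),
            rate_hz=float(round(rate_hz, 6)),
        )


@dataclass
class DerivedSignals:
    """Per-sample quantities derived from a :class:`SensorStream`."""

    t: np.ndarray
    static: np.ndarray                      # (n, 3) g
    dynamic: np.ndarray                     # (n, 3) g
    vedba: Optional[np.ndarray] = None      # (n,) g
    pitch_deg: Optional[np.ndarray] = None
    roll_deg: Optional[np.ndarray] = None
    heading_deg: Optional[np.ndarray] = None


@dataclass
class ActivityBout:
    """A maximal interval in one occupancy state; bouts tile the record."""

    start_s: float
    end_s: float
    state: str                    # "above_ground" | "below_ground"
    evidence: str = "vedba"       # "vedba" | "temperature" | "both"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _running_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centred running mean with a shrinking window at the edges."""
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def split_static_dynamic(stream: SensorStream, window_s: float = 2.0) -> DerivedSignals:
    """Separate gravity (static) from movement (dynamic) acceleration.

    The static component is a centred running mean over ``window_s`` per
    axis (window shrinks at the record edges); the dynamic component is the
    raw signal minus the static one, so static + dynamic == raw exactly.
    """
    w = int(round(window_s * stream.rate_hz))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > len(stream):
        raise ValueError("smoothing window longer than the record")
    if w == len(stream):
        static = np.broadcast_to(stream.acc.mean(axis=0), stream.acc.shape).copy()
    else:
        half = w // 2
        static = np.column_stack(
            [_running_mean(stream.acc[:, k], half) for k in range(3)])
    return DerivedSignals(t=stream.t, static=static, dynamic=stream.acc - static)


def compute_vedba(dynamic: np.ndarray) -> np.ndarray:
    """Vectorial dynamic body acceleration: per-sample L2 norm of the
    dynamic triplets (g).  Invariant to axis permutation and sign flips."""
    dynamic = np.asarray(dynamic, dtype=float)
    return np.sqrt(np.sum(dynamic**2, axis=-1))


def compute_pitch_roll(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and roll (degrees) from the static acceleration triplets."""
    static = np.asarray(static, dtype=float)
    norm = np.linalg.norm(static, axis=-1)
    safe = np.where(norm > 0, norm, 1.0)
    pitch = np.degrees(np.arcsin(np.clip(static[..., 0] / safe, -1.0, 1.0)))
    roll = np.degrees(np.arctan2(-static[..., 1], static[..., 2]))
    return pitch, roll


def compute_heading(
    static: np.ndarray,
    mag: np.ndarray,
    t: Optional[np.ndarray] = None,
    min_static_g: float = 1e-6,
) -> np.ndarray:
    """Tilt-compensated compass heading, degrees clockwise from north.

    The magnetometer triplets are rotated into the horizontal plane using
    pitch/roll from the static acceleration; heading is then
    ``atan2(-m_y, m_x)`` of the levelled field.  The result is unit-free
    (invariant to uniform magnetometer scaling).  Samples with vanishing
    static magnitude have no attitude reference; their heading is
    interpolated from valid neighbours.
    """
    static = np.asarray(static, dtype=float)
    mag = np.asarray(mag, dtype=float)
    pitch, roll = compute_pitch_roll(static)
    th = np.radians(pitch)
    ph = np.radians(roll)

    # De-tilt: m_level = Ry(-pitch) @ Rx(-roll) @ m_body
    mx, my, mz = mag[..., 0], mag[..., 1], mag[..., 2]
    # Rx(-roll)
    my1 = np.cos(ph) * my + np.sin(ph) * mz
    mz1 = -np.sin(ph) * my + np.cos(ph) * mz
    # Ry(-pitch)
    mx2 = np.cos(th) * mx - np.sin(th) * mz1
    heading = np.degrees(np.arctan2(-my1, mx2)) % 360.0

    invalid = np.linalg.norm(static, axis=-1) < min_static_g
    if np.any(invalid):
        if np.all(invalid):
            raise ValueError("no valid attitude samples: static acceleration is zero")
        pos = np.arange(len(heading)) if t is None else np.asarray(t, float)
        rad = np.radians(heading)
        s = np.interp(pos[invalid], pos[~invalid], np.sin(rad[~invalid]))
        c = np.interp(pos[invalid], pos[~invalid], np.cos(rad[~invalid]))
        heading[invalid] = np.degrees(np.arctan2(s, c)) % 360.0
    return heading


def derive_signals(stream: SensorStream, window_s: float = 2.0) -> DerivedSignals:
    """Full derivation: static/dynamic split, VeDBA, pitch/roll, heading."""
    sig = split_static_dynamic(stream, window_s)
    sig.vedba = compute_vedba(sig.dynamic)
    sig.pitch_deg, sig.roll_deg = compute_pitch_roll(sig.static)
    sig.heading_deg = compute_heading(sig.static, stream.mag, t=stream.t)
    return sig


def _runs(mask: np.ndarray) -> list[list]:
    """Maximal runs of constant value: list of [start, stop, value] with
    stop exclusive."""
    n = len(mask)
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [n]])
    return [[int(a), int(b), bool(mask[a])] for a, b in zip(starts, stops)]


def detect_sett_occupancy(
    t: np.ndarray,
    vedba: np.ndarray,
    temperature: Optional[np.ndarray] = None,
    *,
    rate_hz: Optional[float] = None,
    smooth_window_s: float = 5.0,
    vedba_threshold_g: float = 0.1,
    min_bout_s: float = 300.0,
    temp_rise_c: float = 3.0,
    temp_window_s: float = 1800.0,
) -> list[ActivityBout]:
    """Segment a record into above/below-ground bouts.

    VeDBA dampens immediately on entering the sett (from an active level of
    roughly 0.25 g to under 0.1 g) and stays dampened, whereas an animal
    above ground keeps spiking above the threshold even between bursts of
    locomotion.  A below-ground bout is therefore a *continuous* run of
    lightly smoothed VeDBA under ``vedba_threshold_g`` lasting at least
    ``min_bout_s``; shorter dips (pauses above ground) do not qualify, and
    short above-threshold gaps sandwiched between qualifying bouts are
    merged into them.  The smoothing window is short (default 5 s) on
    purpose: it suppresses per-sample noise without averaging brief
    activity bursts away.  A temperature rise of at least ``temp_rise_c``
    within ``temp_window_s`` of a candidate entry corroborates it (evidence
    tag "both"); bout timing always comes from the VeDBA transition because
    the thermometer responds with a lag.
    """
    t = np.asarray(t, dtype=float)
    vedba = np.asarray(vedba, dtype=float)
    if len(t) != len(vedba):
        raise ValueError("time and VeDBA series must be aligned")
    if temperature is not None:
        temperature = np.asarray(temperature, dtype=float)
        if len(temperature) != len(t):
            raise ValueError("temperature series must be aligned with VeDBA")
        if np.all(np.isnan(temperature)):
            temperature = None
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0

    half = max(1, int(round(smooth_window_s * rate_hz)) // 2)
    smoothed = _running_mean(vedba, half)
    below = smoothed < vedba_threshold_g

    min_len = max(1, int(round(min_bout_s * rate_hz)))
    # Qualifying below-ground runs: continuous sub-threshold for >= min_bout.
    mask = np.zeros(len(below), dtype=bool)
    for start, stop, is_below in _runs(below):
        if is_below and stop - start >= min_len:
            mask[start:stop] = True
    # Close short above-ground gaps between qualifying bouts.
    runs = _runs(mask)
    for k, (start, stop, is_below) in enumerate(runs):
        if (not is_below and stop - start < min_len
                and 0 < k < len(runs) - 1):
            mask[start:stop] = True
    runs = _runs(mask)

    dt = 1.0 / rate_hz
    bouts: list[ActivityBout] = []
    for start, stop, is_below in runs:
        t0 = float(t[start])
        t1 = float(t[stop - 1] + dt)
        state = "below_ground" if is_below else "above_ground"
        evidence = "vedba"
        if is_below and temperature is not None:
            j = min(len(t), start + int(round(temp_window_s * rate_hz)))
            window = temperature[start:j]
            if len(window) and np.nanmax(window) - temperature[start] >= temp_rise_c:
                evidence = "both"
        bouts.append(ActivityBout(t0, t1, state, evidence))
    return bouts
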