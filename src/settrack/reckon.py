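"""GPS-enabled dead-reckoning: path integration, gradient calibration,
drift correction.

Speed is taken proportional to VeDBA (``speed = m * VeDBA + c``, clamped at
zero) and integrated along the tilt-compensated heading at the sensor rate.
An initial track built with a nominal gradient drifts; the gradient is then
rescaled so the dead-reckoned displacement between consecutive GPS fixes
matches the GPS-derived displacement in a least-squares sense, and the
remaining per-segment residual is distributed linearly over the samples of
each inter-fix segment so the corrected track passes through every fix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo
from .sensors import ActivityBout, SensorStream, derive_signals, detect_sett_occupancy

__all__ = [
    "SpeedModel",
    "GpsFix",
    "Track",
    "CalibrationError",
    "integrate_path",
    "calibrate_speed_model",
    "gps_correct_track",
    "dead_reckon",
    "DeadReckonConfig",
]


class CalibrationError(RuntimeError):
    """Raised when the speed proxy carries no usable signal."""


@dataclass
class SpeedModel:
    """Linear speed ~ VeDBA model: ``speed = gradient * vedba + intercept``.

    gradient is in m s^-1 per g; predicted speed is clamped at zero.
    ``min_vedba`` is a movement threshold (g): samples below it are treated
    as stationary.  Without it, the low-level dynamic acceleration an
    animal produces while pausing (grooming, snuffling) integrates into
    spurious displacement along the current heading and attenuates the
    calibrated gradient.
    """

    gradient: float = 2.0
    intercept: float = 0.0
    min_vedba: float = 0.05

    def __post_init__(self) -> None:
        if self.gradient <= 0:
            raise ValueError("gradient must be positive")
        if self.intercept < 0:
            raise ValueError("intercept must be non-negative")
        if self.min_vedba < 0:
            raise ValueError("movement threshold must be non-negative")

    def moving(self, vedba: np.ndarray) -> np.ndarray:
        return np.asarray(vedba, float) >= self.min_vedba

    def predict(self, vedba: np.ndarray) -> np.ndarray:
        vedba = np.asarray(vedba, float)
        speed = np.maximum(0.0, self.gradient * vedba + self.intercept)
        return np.where(self.moving(vedba), speed, 0.0)


@dataclass
class GpsFix:
    """One timestamped WGS84 position with nominal horizontal error."""

    time_s: float
    lat: float
    lon: float
    error_m: float = 10.0

    def __post_init__(self) -> None:
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError("invalid coordinates")


@dataclass
class Track:
    """Ordered timestamped positions in a projected frame.

    Geographic coordinates are derived on demand from the projected ones
    under ``epsg``; ``source`` tags provenance (gps | dead_reckoned |
    dead_reckoned_unanchored | truth).
    """

    t: np.ndarray
    easting: np.ndarray
    northing: np.ndarray
    source: str = "dead_reckoned"
    epsg: int = geo.DEFAULT_EPSG
    underground: Optional[np.ndarray] = None
    night: Optional[np.ndarray] = None
    animal: Optional[int] = None
    _lat: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _lon: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.easting, self.northing])

    def _geographic(self) -> tuple[np.ndarray, np.ndarray]:
        if self._lat is None:
            self._lat, self._lon = geo.projected_to_geographic(
                self.easting, self.northing, self.epsg)
        return self._lat, self._lon

    @property
    def lat(self) -> np.ndarray:
        return self._geographic()[0]

    @property
    def lon(self) -> np.ndarray:
        return self._geographic()[1]

    def to_frame(self) -> pd.DataFrame:
        lat, lon = self._geographic()
        df = pd.DataFrame({
            "time_s": self.t, "easting": self.easting, "northing": self.northing,
            "lat": lat, "lon": lon, "source": self.source,
        })
        if self.underground is not None:
            df["underground"] = self.underground
        if self.night is not None:
            df["night"] = self.night
        return df

    @classmethod
    def from_fixes(cls, fixes: Sequence[GpsFix], epsg: int = geo.DEFAULT_EPSG) -> "Track":
        lat = np.array([f.lat for f in fixes], float)
        lon = np.array([f.lon for f in fixes], float)
        e, n = geo.geographic_to_projected(lat, lon, epsg)
        return cls(t=np.array([f.time_s for f in fixes], float),
                   easting=e, northing=n, source="gps", epsg=epsg,
                   _lat=lat, _lon=lon)


def fixes_to_projected(fixes: Sequence[GpsFix], epsg: int = geo.DEFAULT_EPSG
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(times, (k,2) positions) of fixes in the projected frame."""
    times = np.array([f.time_s for f in fixes], float)
    lat = np.array([f.lat for f in fixes], float)
    lon = np.array([f.lon for f in fixes], float)
    e, n = geo.geographic_to_projected(lat, lon, epsg)
    return times, np.column_stack([e, n])


def _heading_unit(heading_deg: np.ndarray) -> np.ndarray:
    h = np.radians(np.asarray(heading_deg, float))
    return np.column_stack([np.sin(h), np.cos(h)])  # (east, north)


def integrate_path(
    vedba: np.ndarray,
    heading_deg: np.ndarray,
    model: SpeedModel,
    start: tuple[float, float] = (0.0, 0.0),
    dt: float = 1.0 / 40.0,
    t: Optional[np.ndarray] = None,
    underground: Optional[np.ndarray] = None,
    epsg: int = geo.DEFAULT_EPSG,
    source: str = "dead_reckoned",
) -> Track:
    """Integrate speed-from-VeDBA along heading from ``start``.

    Sample i contributes a step ``speed_i * dt`` at azimuth ``heading_i``
    (east = sin, north = cos); below-ground samples contribute nothing.
    """
    vedba = np.asarray(vedba, float)
    heading_deg = np.asarray(heading_deg, float)
    if vedba.shape != heading_deg.shape:
        raise ValueError("vedba and heading must have the same length")
    speed = model.predict(vedba)
    if underground is not None:
        speed = np.where(np.asarray(underground, bool), 0.0, speed)
    steps = speed[:, None] * dt * _heading_unit(heading_deg)
    pos = np.asarray(start, float) + np.cumsum(steps, axis=0)
    if t is None:
        t = np.arange(1, len(vedba) + 1) * dt
    return Track(t=np.asarray(t, float), easting=pos[:, 0], northing=pos[:, 1],
                 source=source, epsg=epsg,
                 underground=None if underground is None
                 else np.asarray(underground, bool))


def calibrate_speed_model(
    t: np.ndarray,
    vedba: np.ndarray,
    heading_deg: np.ndarray,
    fixes: Sequence[GpsFix],
    initial: SpeedModel,
    dt: float = 1.0 / 40.0,
    underground: Optional[np.ndarray] = None,
    epsg: int = geo.DEFAULT_EPSG,
    rel_tol: float = 1e-4,
    max_iter: int = 50,
) -> tuple[SpeedModel, pd.DataFrame]:
    """Rescale the speed gradient so dead-reckoned and GPS displacements accord.

    Time-matches each GPS fix to the sensor record, then iteratively
    rescales the gradient so the summed dead-reckoned displacement vector
    over each inter-fix segment matches the GPS displacement in the
    least-squares sense, stopping at relative change < ``rel_tol`` (at most
    ``max_iter`` iterations; with a zero intercept the update lands on the
    least-squares optimum immediately).  Returns the fitted model and a
    per-segment residual report.
    """
    t = np.asarray(t, float)
    vedba = np.asarray(vedba, float)
    vedba = np.where(initial.moving(vedba), vedba, 0.0)
    if underground is not None:
        vedba = np.where(np.asarray(underground, bool), 0.0, vedba)
    if len(fixes) < 2:
        raise ValueError("need at least 2 GPS fixes to calibrate")
    fix_t, fix_pos = fixes_to_projected(fixes, epsg)
    order = np.argsort(fix_t)
    fix_t, fix_pos = fix_t[order], fix_pos[order]

    inside = (fix_t >= t[0] - dt) & (fix_t <= t[-1] + dt)
    if inside.sum() < 2:
        raise ValueError("need at least 2 GPS fixes within the sensor record")
    fix_t, fix_pos = fix_t[inside], fix_pos[inside]

    u = _heading_unit(heading_deg)
    step_v = vedba[:, None] * dt * u          # displacement per unit gradient
    step_c = dt * u                           # displacement per unit intercept
    cum_v = np.vstack([[0.0, 0.0], np.cumsum(step_v, axis=0)])
    cum_c = np.vstack([[0.0, 0.0], np.cumsum(step_c, axis=0)])
    # Sample i's step lands at time t[i] (position includes that step), so
    # the cumulative index matching a fix at t[i] is i + 1.
    idx = np.searchsorted(t, fix_t + dt / 2)
    idx = np.clip(idx, 0, len(t))

    seg_v = cum_v[idx[1:]] - cum_v[idx[:-1]]  # (k-1, 2) per unit gradient
    seg_c = cum_c[idx[1:]] - cum_c[idx[:-1]]
    seg_gps = fix_pos[1:] - fix_pos[:-1]

    denom = float(np.sum(seg_v * seg_v))
    if denom == 0.0:
        if np.linalg.norm(seg_gps) > 0:
            raise CalibrationError(
                "VeDBA is zero everywhere but GPS shows displacement: "
                "the speed proxy carries no signal")
        return replace(initial), pd.DataFrame(
            columns=["t_start", "t_end", "residual_m", "gps_dist_m"])

    m = initial.gradient
    c = initial.intercept
    for _ in range(max_iter):
        target = seg_gps - c * seg_c
        m_new = float(np.sum(seg_v * target)) / denom
        if m_new <= 0:
            raise CalibrationError("calibration drove the gradient non-positive")
        if abs(m_new - m) <= rel_tol * abs(m):
            m = m_new
            break
        m = m_new

    fitted = SpeedModel(gradient=m, intercept=c, min_vedba=initial.min_vedba)
    seg_dr = m * seg_v + c * seg_c
    report = pd.DataFrame({
        "t_start": fix_t[:-1],
        "t_end": fix_t[1:],
        "residual_m": np.linalg.norm(seg_dr - seg_gps, axis=1),
        "gps_dist_m": np.linalg.norm(seg_gps, axis=1),
    })
    return fitted, report


def gps_correct_track(dr: Track, fixes: Sequence[GpsFix]) -> Track:
    """Distribute DR-vs-GPS residuals so the track passes through every fix.

    Within each inter-fix segment the correction is linear in time between
    the residual at the bracketing fixes (current-style correction), which
    preserves the dead-reckoned turn structure up to an affine shift.
    Before the first and after the last usable fix a constant offset is
    applied.  Fixes outside the track's time span are skipped with a
    warning.
    """
    if len(fixes) == 0:
        return dr
    fix_t, fix_pos = fixes_to_projected(fixes, dr.epsg)
    order = np.argsort(fix_t)
    fix_t, fix_pos = fix_t[order], fix_pos[order]
    dt = float(np.median(np.diff(dr.t))) if len(dr) > 1 else 0.0
    inside = (fix_t >= dr.t[0] - dt / 2) & (fix_t <= dr.t[-1] + dt / 2)
    if not inside.all():
        warnings.warn(f"skipping {int((~inside).sum())} GPS fix(es) outside "
                      "the track time span")
    fix_t, fix_pos = fix_t[inside], fix_pos[inside]
    if len(fix_t) == 0:
        return dr

    # Residual at each fix: GPS position minus DR position at the fix time.
    dr_e = np.interp(fix_t, dr.t, dr.easting)
    dr_n = np.interp(fix_t, dr.t, dr.northing)
    res = fix_pos - np.column_stack([dr_e, dr_n])

    # Piecewise-linear residual in time, held constant beyond the end fixes.
    corr_e = np.interp(dr.t, fix_t, res[:, 0])
    corr_n = np.interp(dr.t, fix_t, res[:, 1])
    return Track(
        t=dr.t, easting=dr.easting + corr_e, northing=dr.northing + corr_n,
        source=dr.source, epsg=dr.epsg, underground=dr.underground,
        night=dr.night, animal=dr.animal)


@dataclass
class DeadReckonConfig:
    """Parameters for the end-to-end dead-reckoning of one night."""

    initial_model: SpeedModel = field(default_factory=SpeedModel)
    static_window_s: float = 2.0
    epsg: int = geo.DEFAULT_EPSG
    calibrate: bool = True
    occupancy_kwargs: dict = field(default_factory=dict)


def dead_reckon(
    stream: SensorStream,
    fixes: Sequence[GpsFix],
    bouts: Optional[Sequence[ActivityBout]] = None,
    config: Optional[DeadReckonConfig] = None,
) -> Track:
    """Reconstruct one night's above-ground track from raw sensors and GPS.

    Orchestrates the static/dynamic split, VeDBA, heading, sett-occupancy
    detection (unless ``bouts`` is supplied), per-night gradient
    calibration, path integration and GPS correction.  Below-ground
    intervals are excluded from the output; GPS fixes falling below ground
    are discarded before calibration.  With no usable fixes, the uncorrected
    track is returned tagged ``dead_reckoned_unanchored``.
    """
    config = config or DeadReckonConfig()
    sig = derive_signals(stream, config.static_window_s)
    if bouts is None:
        bouts = detect_sett_occupancy(
            stream.t, sig.vedba, stream.temp, rate_hz=stream.rate_hz,
            **config.occupancy_kwargs)
    underground = np.zeros(len(stream), dtype=bool)
    for b in bouts:
        if b.state == "below_ground":
            underground |= (stream.t >= b.start_s) & (stream.t < b.end_s)
    if underground.all():
        return Track(t=np.empty(0), easting=np.empty(0), northing=np.empty(0),
                     source="dead_reckoned", epsg=config.epsg)

    # Discard fixes recorded below ground (no sky view in a real sett, and
    # they would anchor the track to stale positions).
    usable = []
    for f in fixes:
        i = int(np.clip(np.searchsorted(stream.t, f.time_s), 0, len(stream) - 1))
        if not underground[i]:
            usable.append(f)

    model = config.initial_model
    if config.calibrate and len(usable) >= 2:
        model, _ = calibrate_speed_model(
            stream.t, sig.vedba, sig.heading_deg, usable, model,
            dt=stream.dt, underground=underground, epsg=config.epsg)

    dr = integrate_path(
        sig.vedba, sig.heading_deg, model, start=(0.0, 0.0), dt=stream.dt,
        t=stream.t, underground=underground, epsg=config.epsg)
    if len(usable) >= 1:
        dr = gps_correct_track(dr, usable)
        source = "dead_reckoned"
    else:
        source = "dead_reckoned_unanchored"

    keep = ~underground
    return Track(t=dr.t[keep], easting=dr.easting[keep],
                 northing=dr.northing[keep], source=source, epsg=config.epsg,
                 underground=underground[keep])
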