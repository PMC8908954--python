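"""Dead-reckoning: integration, gradient calibration, GPS correction."""

import numpy as np
import pytest

from settrack import geo
from settrack.reckon import (
    CalibrationError,
    DeadReckonConfig,
    GpsFix,
    SpeedModel,
    Track,
    calibrate_speed_model,
    dead_reckon,
    fixes_to_projected,
    gps_correct_track,
    integrate_path,
)
from settrack.sensors import derive_signals


def fix_at(e, n, t, epsg=geo.DEFAULT_EPSG):
    lat, lon = geo.projected_to_geographic(e, n, epsg)
    return GpsFix(time_s=t, lat=float(lat), lon=float(lon))


class TestIntegrate:
    def test_zero_vedba_stays_at_start(self):
        tr = integrate_path(np.zeros(100), np.zeros(100),
                            SpeedModel(2.0, 0.0), start=(10.0, 20.0))
        assert np.all(tr.easting == 10.0)
        assert np.all(tr.northing == 20.0)

    def test_north_endpoint(self):
        n = 3600 * 40
        tr = integrate_path(np.full(n, 0.25), np.zeros(n),
                            SpeedModel(2.0, 0.0), start=(0.0, 0.0))
        assert tr.northing[-1] == pytest.approx(1800.0, rel=1e-9)
        assert tr.easting[-1] == pytest.approx(0.0, abs=1e-6)

    def test_east_endpoint(self):
        n = 3600 * 40
        tr = integrate_path(np.full(n, 0.25), np.full(n, 90.0),
                            SpeedModel(2.0, 0.0), start=(0.0, 0.0))
        assert tr.easting[-1] == pytest.approx(1800.0, rel=1e-9)

    def test_underground_contributes_nothing(self):
        n = 1000
        under = np.zeros(n, bool)
        under[500:] = True
        tr = integrate_path(np.full(n, 0.25), np.zeros(n),
                            SpeedModel(2.0, 0.0), underground=under)
        assert tr.northing[-1] == pytest.approx(tr.northing[499])

    def test_movement_threshold_zeroes_slow_samples(self):
        model = SpeedModel(2.0, 0.0, min_vedba=0.05)
        assert np.all(model.predict(np.array([0.04, 0.0])) == 0.0)
        assert model.predict(np.array([0.25]))[0] == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            integrate_path(np.zeros(5), np.zeros(6), SpeedModel())


def synthetic_signals(m_true=2.0, n_per_seg=2000, n_seg=6, dt=0.025, seed=0):
    """VeDBA/heading with known gradient and exact fix positions."""
    rng = np.random.default_rng(seed)
    vedba = rng.uniform(0.1, 0.3, n_per_seg * n_seg)
    heading = rng.uniform(0, 360, n_seg).repeat(n_per_seg)
    t = np.arange(len(vedba)) * dt
    speed = m_true * vedba
    h = np.radians(heading)
    pos = np.cumsum(np.column_stack([speed * dt * np.sin(h),
                                     speed * dt * np.cos(h)]), axis=0)
    e0, n0 = 500000.0, 6020000.0
    fixes = [fix_at(e0 + pos[0, 0], n0 + pos[0, 1], t[0])]
    for k in range(1, n_seg + 1):
        i = k * n_per_seg - 1
        fixes.append(fix_at(e0 + pos[i, 0], n0 + pos[i, 1], t[i]))
    return t, vedba, heading, fixes


class TestCalibration:
    def test_fixed_point_when_displacements_accord(self):
        t, vedba, heading, fixes = synthetic_signals(m_true=2.0)
        model, report = calibrate_speed_model(
            t, vedba, heading, fixes, SpeedModel(2.0, 0.0, min_vedba=0.0))
        assert model.gradient == pytest.approx(2.0, rel=1e-6)
        assert report["residual_m"].max() < 1e-3

    def test_recovers_generating_gradient_from_wrong_start(self):
        t, vedba, heading, fixes = synthetic_signals(m_true=2.0)
        model, _ = calibrate_speed_model(
            t, vedba, heading, fixes, SpeedModel(0.5, 0.0, min_vedba=0.0))
        assert model.gradient == pytest.approx(2.0, rel=1e-6)

    def test_scale_equivariance_doubling_vedba_halves_gradient(self):
        t, vedba, heading, fixes = synthetic_signals()
        m1, _ = calibrate_speed_model(t, vedba, heading, fixes,
                                      SpeedModel(1.0, 0.0, min_vedba=0.0))
        m2, _ = calibrate_speed_model(t, 2 * vedba, heading, fixes,
                                      SpeedModel(1.0, 0.0, min_vedba=0.0))
        assert m2.gradient == pytest.approx(m1.gradient / 2.0, rel=1e-9)

    def test_zero_vedba_with_displacement_is_error(self):
        t = np.arange(1000) * 0.025
        fixes = [fix_at(500000.0, 6020000.0, 0.0),
                 fix_at(500100.0, 6020000.0, t[-1])]
        with pytest.raises(CalibrationError):
            calibrate_speed_model(t, np.zeros(1000), np.zeros(1000), fixes,
                                  SpeedModel(2.0))

    def test_needs_two_fixes(self):
        t = np.arange(100) * 0.025
        with pytest.raises(ValueError):
            calibrate_speed_model(t, np.ones(100), np.zeros(100),
                                  [fix_at(500000.0, 6020000.0, 0.0)],
                                  SpeedModel())


class TestCorrection:
    def test_zero_residual_is_identity(self):
        t, vedba, heading, fixes = synthetic_signals()
        dr = integrate_path(vedba, heading, SpeedModel(2.0, 0.0, min_vedba=0.0),
                            start=(500000.0, 6020000.0), t=t)
        out = gps_correct_track(dr, fixes)
        assert np.allclose(out.easting, dr.easting, atol=1e-6)
        assert np.allclose(out.northing, dr.northing, atol=1e-6)

    def test_constant_drift_midpoint_half_residual(self):
        # DR with uniform velocity bias between two fixes: the closed form
        # of linear error distribution shifts the midpoint by res/2.
        n = 101
        t = np.arange(n, dtype=float)
        e0, n0 = 500000.0, 6020000.0
        drift = 0.5  # m/s east bias
        dr = Track(t=t, easting=e0 + drift * t, northing=np.full(n, n0))
        fixes = [fix_at(e0, n0, 0.0), fix_at(e0, n0, 100.0)]  # truth: no move
        out = gps_correct_track(dr, fixes)
        assert out.easting[0] == pytest.approx(e0, abs=1e-6)
        assert out.easting[-1] == pytest.approx(e0, abs=1e-6)
        # midpoint: dr had +25 m; residual at end is -50 m; corrected -> +0
        assert out.easting[50] == pytest.approx(e0 + 25.0 - 25.0, abs=1e-6)

    def test_fix_outside_span_skipped_with_warning(self):
        n = 100
        dr = Track(t=np.arange(n, dtype=float),
                   easting=np.full(n, 500000.0), northing=np.full(n, 6020000.0))
        with pytest.warns(UserWarning, match="outside"):
            out = gps_correct_track(dr, [fix_at(500010.0, 6020000.0, 50.0),
                                         fix_at(500000.0, 6020000.0, 1e6)])
        assert np.allclose(out.easting, 500010.0)

    def test_anchoring_through_every_fix(self):
        t, vedba, heading, fixes = synthetic_signals()
        dr = integrate_path(vedba, heading, SpeedModel(1.3, 0.0, min_vedba=0.0),
                            start=(500000.0, 6020000.0), t=t)
        out = gps_correct_track(dr, fixes)
        ft, fp = fixes_to_projected(fixes)
        for k in range(len(fixes)):
            e = np.interp(ft[k], out.t, out.easting)
            n = np.interp(ft[k], out.t, out.northing)
            assert float(np.hypot(e - fp[k, 0], n - fp[k, 1])) < 1e-6


class TestDeadReckonEndToEnd:
    def test_track_passes_fixes_and_beats_gps_interp(self, fast_night):
        tr, stream, fixes = (fast_night["track"], fast_night["stream"],
                             fast_night["fixes"])
        out = dead_reckon(stream, fixes)
        assert out.source == "dead_reckoned"
        ft, fp = fixes_to_projected(fixes)
        for k in range(len(fixes)):
            i = int(np.argmin(np.abs(out.t - ft[k])))
            if abs(out.t[i] - ft[k]) < 1e-6:  # fix not inside a detected bout gap
                d = float(np.hypot(out.easting[i] - fp[k, 0],
                                   out.northing[i] - fp[k, 1]))
                assert d < 1e-6
        keep = ~tr.underground
        e = np.interp(tr.t[keep], out.t, out.easting)
        n = np.interp(tr.t[keep], out.t, out.northing)
        dr_rms = np.sqrt(np.mean((e - tr.easting[keep]) ** 2
                                 + (n - tr.northing[keep]) ** 2))
        ge = np.interp(tr.t[keep], ft, fp[:, 0])
        gn = np.interp(tr.t[keep], ft, fp[:, 1])
        gps_rms = np.sqrt(np.mean((ge - tr.easting[keep]) ** 2
                                  + (gn - tr.northing[keep]) ** 2))
        assert dr_rms < gps_rms

    def test_no_fixes_returns_unanchored(self, fast_night):
        out = dead_reckon(fast_night["stream"], [])
        assert out.source == "dead_reckoned_unanchored"
        assert len(out) > 0

    def test_all_underground_gives_empty_track(self):
        from tests.conftest import fast_config
        from settrack.simulate import render_sensor_streams, simulate_true_track
        cfg = fast_config(emergence_h=(23.5, 23.6), return_dash_h=(23.7, 23.8))
        tr = simulate_true_track(cfg, animal=0)
        stream = render_sensor_streams(tr, cfg)
        out = dead_reckon(stream, [])
        assert len(out) == 0

    def test_corrected_dr_path_at_least_gps_polyline(self, fast_night):
        # The GPS polyline is the shortest path through the anchor points,
        # so the corrected dead-reckoned path cannot be shorter.
        from settrack.spaceuse import path_length
        stream, fixes = fast_night["stream"], fast_night["fixes"]
        out = dead_reckon(stream, fixes)
        gps_tr = Track.from_fixes(fixes)
        assert path_length(out) >= path_length(gps_tr)


def test_track_projected_geographic_consistency(fast_night):
    out = dead_reckon(fast_night["stream"], fast_night["fixes"])
    e, n = geo.geographic_to_projected(out.lat, out.lon, out.epsg)
    assert np.abs(e - out.easting).max() < 0.01
    assert np.abs(n - out.northing).max() < 0.01
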