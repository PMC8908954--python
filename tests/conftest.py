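"""Shared fixtures: a fast small-scale simulation for unit tests and a
session-scoped full-scale study (two animals, seven nights) for the
end-to-end property checks."""

from __future__ import annotations

import numpy as np
import pytest

from settrack.pipeline import AnalysisConfig, SimConfig, analyse_bundle, simulate_bundle


def fast_config(**overrides) -> SimConfig:
    """A two-hour single night at 20 Hz: cheap but fully featured."""
    defaults = dict(
        seed=123,
        n_animals=1,
        n_nights=1,
        record_start_h=21.0,
        record_end_h=23.0,
        emergence_h=(21.05, 21.15),
        return_dash_h=(22.7, 22.8),
        gps_start_h=21.0,
        gps_end_h=23.0,
        gps_interval_s=600.0,
        sample_rate_hz=20.0,
        p_midnight_bout=0.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def fast_cfg() -> SimConfig:
    return fast_config()


@pytest.fixture(scope="session")
def fast_night(fast_cfg):
    """One simulated fast night with rendered sensors and GPS."""
    from settrack.simulate import render_sensor_streams, sample_gps, simulate_true_track

    track = simulate_true_track(fast_cfg, animal=0)
    stream = render_sensor_streams(track, fast_cfg)
    fixes, schedule = sample_gps(track, fast_cfg)
    return {"cfg": fast_cfg, "track": track, "stream": stream,
            "fixes": fixes, "schedule": schedule}


@pytest.fixture(scope="session")
def full_study():
    """The full synthetic study at study conditions: 2 animals x 7 nights,
    40 Hz sensors, hourly GPS with 10 m error, analysed end to end."""
    cfg = SimConfig(seed=42)
    bundle = simulate_bundle(cfg)
    result = analyse_bundle(bundle, AnalysisConfig())
    return {"cfg": cfg, "bundle": bundle, "result": result}
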