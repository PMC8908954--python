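"""End-to-end orchestration: simulate a study, analyse it, write artefacts.

``run_simulate`` writes the synthetic study to disk (sensor CSVs, GPS
CSVs/GPX, landscape GeoJSON, ground-truth CSVs and a hashed manifest);
``run_analyse`` reads those files back — or an in-memory bundle — and
produces per-night tracks and bouts, the night-metric table, home ranges,
proximity budgets, the statistical comparisons and a plain-text summary.
Nights are delimited by the detected above-ground bouts; all randomness
derives from the single root seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import geo
from .reckon import DeadReckonConfig, SpeedModel, Track, dead_reckon
from .sensors import SensorStream, derive_signals, detect_sett_occupancy
from .simulate import (
    LandscapeLayer,
    SimConfig,
    TrueTrack,
    generate_landscape,
    read_gps_csv,
    render_sensor_streams,
    sample_gps,
    simulate_true_track,
    write_gps_csv,
    write_gpx,
)
from .spaceuse import (
    HomeRange,
    kde_home_range,
    mcp_area,
    path_length,
    proximity_times,
    trim_outliers,
)
from .stats import TestResult, landuse_model, paired_comparison, welch_comparison

log = logging.getLogger("settrack")

PROP_COLS = ["prop_field", "prop_hedge", "prop_building", "prop_road"]


@dataclass
class AnalysisConfig:
    """Stage parameters for the analysis half of the pipeline."""

    static_window_s: float = 2.0
    initial_gradient: float = 2.0
    initial_intercept: float = 0.0
    min_vedba_g: float = 0.05
    smooth_window_s: float = 5.0
    vedba_threshold_g: float = 0.1
    min_bout_s: float = 300.0
    temp_rise_c: float = 3.0
    temp_window_s: float = 1800.0
    trim_fraction: float = 0.05
    kde_bandwidth: str | float = "reference"
    kde_grid_res: int = 200
    proximity_radius_m: float = 20.0
    gps_fix_dwell_s: float = 3600.0
    epsg: int = geo.DEFAULT_EPSG
    gps_only: bool = False


@dataclass
class RunConfig:
    """Whole-run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "settrack_out"
    simulation: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": self.outdir,
                "simulation": dataclasses.asdict(self.simulation),
                "analysis": dataclasses.asdict(self.analysis)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim_d = dict(d.get("simulation", {}))
        for f in dataclasses.fields(SimConfig):
            if isinstance(f.default, tuple) and f.name in sim_d:
                sim_d[f.name] = tuple(sim_d[f.name])
        return cls(seed=int(d.get("seed", 0)),
                   outdir=str(d.get("outdir", "settrack_out")),
                   simulation=SimConfig(**sim_d),
                   analysis=AnalysisConfig(**d.get("analysis", {})))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class AnimalData:
    animal: int
    truth: Optional[TrueTrack]
    streams: dict              # night -> SensorStream
    fixes: list

    def night_fixes(self, sim: SimConfig, night: int) -> list:
        lo = night * 86400.0 + sim.record_start_h * 3600.0
        hi = night * 86400.0 + sim.record_end_h * 3600.0
        return [f for f in self.fixes if lo <= f.time_s <= hi]


@dataclass
class SimBundle:
    config: SimConfig
    landscape: LandscapeLayer
    animals: list


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Simulate the whole study in memory (all animals, all nights)."""
    landscape = generate_landscape(config)
    animals = []
    for a in range(config.n_animals):
        truth = simulate_true_track(config, animal=a)
        streams = {int(k): render_sensor_streams(truth.select_night(int(k)), config)
                   for k in truth.night_ids()}
        fixes, _ = sample_gps(truth, config)
        animals.append(AnimalData(animal=a, truth=truth, streams=streams,
                                  fixes=fixes))
    return SimBundle(config=config, landscape=landscape, animals=animals)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(config: RunConfig, bundle: Optional[SimBundle] = None) -> dict:
    """Write the synthetic study to ``config.outdir``; return the manifest."""
    out = Path(config.outdir)
    if not out.exists():
        out.mkdir(parents=True)
        log.info("created output directory %s", out)
    sim = config.simulation
    bundle = bundle or simulate_bundle(sim)
    epoch = sim.epoch()

    files: dict[str, str] = {}
    land_path = out / "landscape.geojson"
    bundle.landscape.write_geojson(land_path)
    files[land_path.name] = _sha256(land_path)
    for ad in bundle.animals:
        for night, stream in sorted(ad.streams.items()):
            p = out / f"animal{ad.animal}_night{night}_sensors.csv"
            stream.write_csv(p)
            files[p.name] = _sha256(p)
        p = out / f"animal{ad.animal}_gps.csv"
        write_gps_csv(ad.fixes, p, epoch)
        files[p.name] = _sha256(p)
        p = out / f"animal{ad.animal}_gps.gpx"
        write_gpx(ad.fixes, p, epoch)
        files[p.name] = _sha256(p)
        p = out / f"animal{ad.animal}_truth.csv"
        ad.truth.write_csv(p)
        files[p.name] = _sha256(p)

    param_blob = json.dumps(dataclasses.asdict(sim), sort_keys=True)
    manifest = {
        "parameters": dataclasses.asdict(sim),
        "parameter_hash": hashlib.sha256(param_blob.encode()).hexdigest(),
        "files": files,
        "n_animals": sim.n_animals,
        "n_nights": sim.n_nights,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_bundle(config: RunConfig) -> SimBundle:
    """Reconstruct a bundle from files written by :func:`run_simulate`."""
    out = Path(config.outdir)
    sim = config.simulation
    epoch = sim.epoch()
    landscape = LandscapeLayer.from_geojson(out / "landscape.geojson")
    animals = []
    a = 0
    while (out / f"animal{a}_gps.csv").exists() or any(
            out.glob(f"animal{a}_night*_sensors.csv")):
        streams = {}
        for p in sorted(out.glob(f"animal{a}_night*_sensors.csv")):
            night = int(p.stem.split("_")[1].removeprefix("night"))
            streams[night] = SensorStream.read_csv(p)
        fixes = []
        if (out / f"animal{a}_gps.csv").exists():
            fixes = read_gps_csv(out / f"animal{a}_gps.csv", epoch)
        truth = None
        tp = out / f"animal{a}_truth.csv"
        if tp.exists():
            df = pd.read_csv(tp)
            from .simulate import STATE_NAMES
            codes = {s: i for i, s in enumerate(STATE_NAMES)}
            truth = TrueTrack(
                t=df["time_s"].to_numpy(float),
                easting=df["easting"].to_numpy(float),
                northing=df["northing"].to_numpy(float),
                speed=df["speed_ms"].to_numpy(float),
                heading_deg=df["heading_deg"].to_numpy(float),
                state=df["state"].map(codes).to_numpy(np.int8),
                night=df["night"].to_numpy(np.int16),
                animal=a, epsg=sim.epsg)
        animals.append(AnimalData(animal=a, truth=truth, streams=streams,
                                  fixes=fixes))
        a += 1
    if not animals:
        raise FileNotFoundError(f"no study files found under {out}")
    return SimBundle(config=sim, landscape=landscape, animals=animals)


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame            # one row per (animal, night, source)
    home_ranges: list                # HomeRange objects
    budgets: list                    # ProximityBudget objects
    tests: pd.DataFrame              # flattened TestResults
    tukey: pd.DataFrame              # pairwise contrasts per source
    accuracy: Optional[pd.DataFrame]
    dr_tracks: dict                  # (animal, night) -> Track
    gps_tracks: dict                 # (animal, night) -> Track
    summary: str


def _night_gps_track(fixes: list, epsg: int, animal: int) -> Optional[Track]:
    if not fixes:
        return None
    tr = Track.from_fixes(fixes, epsg)
    tr.animal = animal
    return tr


def analyse_bundle(bundle: SimBundle, acfg: Optional[AnalysisConfig] = None
                   ) -> AnalysisResult:
    """Run the full analysis on a simulated or loaded study bundle."""
    acfg = acfg or AnalysisConfig()
    sim = bundle.config
    drcfg = DeadReckonConfig(
        initial_model=SpeedModel(acfg.initial_gradient, acfg.initial_intercept,
                                 acfg.min_vedba_g),
        static_window_s=acfg.static_window_s, epsg=acfg.epsg,
        occupancy_kwargs=dict(
            smooth_window_s=acfg.smooth_window_s,
            vedba_threshold_g=acfg.vedba_threshold_g,
            min_bout_s=acfg.min_bout_s, temp_rise_c=acfg.temp_rise_c,
            temp_window_s=acfg.temp_window_s))

    rows = []
    acc_rows = []
    dr_tracks: dict = {}
    gps_tracks: dict = {}
    for ad in bundle.animals:
        for night, stream in sorted(ad.streams.items()):
            fixes = ad.night_fixes(sim, night)
            gps_tr = _night_gps_track(fixes, acfg.epsg, ad.animal)
            if gps_tr is not None:
                gps_tracks[(ad.animal, night)] = gps_tr

            sig = derive_signals(stream, acfg.static_window_s)
            bouts = detect_sett_occupancy(
                stream.t, sig.vedba, stream.temp, rate_hz=stream.rate_hz,
                smooth_window_s=acfg.smooth_window_s,
                vedba_threshold_g=acfg.vedba_threshold_g,
                min_bout_s=acfg.min_bout_s, temp_rise_c=acfg.temp_rise_c,
                temp_window_s=acfg.temp_window_s)
            above_s = sum(b.duration_s for b in bouts
                          if b.state == "above_ground")

            dr_tr = None
            if not acfg.gps_only:
                dr_tr = dead_reckon(stream, fixes, bouts=bouts, config=drcfg)
                dr_tr.animal = ad.animal
                if len(dr_tr):
                    dr_tracks[(ad.animal, night)] = dr_tr
            elif not fixes:
                log.warning("animal %d night %d: no data at all",
                            ad.animal, night)

            for source, tr in (("gps", gps_tr), ("dead_reckoned", dr_tr)):
                if tr is None or len(tr) == 0:
                    continue
                budget = proximity_times(
                    tr, bundle.landscape, radius_m=acfg.proximity_radius_m,
                    gps_fix_dwell_s=acfg.gps_fix_dwell_s, night=night)
                row = {"animal": ad.animal, "night": night, "source": source,
                       "path_km": path_length(tr),
                       "above_ground_s": above_s,
                       "n_points": len(tr)}
                for cls in ("field", "hedge", "building", "road"):
                    row[f"prop_{cls}"] = budget.proportions[cls]
                    row[f"time_{cls}_s"] = budget.times_s[cls]
                rows.append(row)

            if ad.truth is not None:
                nt = ad.truth.select_night(night)
                keep = ~nt.underground
                if keep.any():
                    if dr_tr is not None and len(dr_tr) > 1:
                        e = np.interp(nt.t[keep], dr_tr.t, dr_tr.easting)
                        nn = np.interp(nt.t[keep], dr_tr.t, dr_tr.northing)
                        dr_rms = float(np.sqrt(np.mean(
                            (e - nt.easting[keep])**2 + (nn - nt.northing[keep])**2)))
                    else:
                        dr_rms = np.nan
                    if gps_tr is not None and len(gps_tr) > 1:
                        ge = np.interp(nt.t[keep], gps_tr.t, gps_tr.easting)
                        gn = np.interp(nt.t[keep], gps_tr.t, gps_tr.northing)
                        gps_rms = float(np.sqrt(np.mean(
                            (ge - nt.easting[keep])**2 + (gn - nt.northing[keep])**2)))
                    else:
                        gps_rms = np.nan
                    acc_rows.append({"animal": ad.animal, "night": night,
                                     "dr_rms_m": dr_rms,
                                     "gps_interp_rms_m": gps_rms})

    metrics = pd.DataFrame(rows)
    budgets = []  # kept per-night inside metrics; budgets list for API users
    home_ranges: list[HomeRange] = []
    for ad in bundle.animals:
        for source, tracks in (("gps", gps_tracks), ("dead_reckoned", dr_tracks)):
            pts = [t.positions for (a, _), t in tracks.items() if a == ad.animal]
            if not pts:
                continue
            pts = np.vstack(pts)
            if len(pts) >= 3:
                hr = mcp_area(pts, level=1.0 - acfg.trim_fraction, source=source)
                hr.metadata["animal"] = ad.animal
                home_ranges.append(hr)
            if len(pts) >= 30:
                trimmed = trim_outliers(pts, acfg.trim_fraction)
                hr = kde_home_range(trimmed, bandwidth=acfg.kde_bandwidth,
                                    grid_res=acfg.kde_grid_res, source=source)
                hr.trim_fraction = acfg.trim_fraction
                hr.metadata["animal"] = ad.animal
                home_ranges.append(hr)

    tests, tukey = _run_stats(metrics)
    accuracy = pd.DataFrame(acc_rows) if acc_rows else None
    summary = _summarise(metrics, home_ranges, tests, accuracy)
    return AnalysisResult(metrics=metrics, home_ranges=home_ranges,
                          budgets=budgets, tests=tests, tukey=tukey,
                          accuracy=accuracy, dr_tracks=dr_tracks,
                          gps_tracks=gps_tracks, summary=summary)


def _result_row(name: str, res: TestResult, extra: Optional[dict] = None) -> dict:
    row = {"comparison": name, "test": res.test, "statistic": res.statistic,
           "df": res.df, "p_value": res.p_value, "flag": res.flag}
    row.update(extra or {})
    return row


def _run_stats(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    tukey_rows = []
    if metrics.empty:
        return pd.DataFrame(), pd.DataFrame()
    wide = metrics.pivot_table(index=["animal", "night"], columns="source",
                               values=["path_km"] + PROP_COLS)

    # GPS vs dead-reckoned, paired over badger-nights.
    for metric in ["path_km"] + PROP_COLS:
        if metric not in wide or not {"gps", "dead_reckoned"} <= set(
                wide[metric].columns):
            continue
        sub = wide[metric].dropna()
        if len(sub) >= 2:
            res = paired_comparison(sub["dead_reckoned"], sub["gps"])
            rows.append(_result_row(f"dr_vs_gps:{metric}", res, {
                "mean_dr": sub["dead_reckoned"].mean(),
                "mean_gps": sub["gps"].mean()}))

    # Between animals, per source (Welch).
    animals = sorted(metrics["animal"].unique())
    if len(animals) == 2:
        for source in metrics["source"].unique():
            for metric in ["path_km"] + PROP_COLS:
                a = metrics.query("animal == @animals[0] and source == @source")[metric]
                b = metrics.query("animal == @animals[1] and source == @source")[metric]
                if len(a) >= 2 and len(b) >= 2:
                    res = welch_comparison(a, b)
                    rows.append(_result_row(
                        f"animals:{source}:{metric}", res))

    # Land use: one-way model + Tukey HSD per source.
    for source in metrics["source"].unique():
        sub = metrics[metrics["source"] == source]
        long = sub.melt(id_vars=["animal", "night"],
                        value_vars=PROP_COLS, var_name="feature_class",
                        value_name="value")
        long["feature_class"] = long["feature_class"].str.removeprefix("prop_")
        try:
            overall, pairs = landuse_model(long)
        except ValueError:
            continue
        rows.append(_result_row(f"landuse:{source}", overall))
        pairs = pairs.assign(source=source)
        tukey_rows.append(pairs)

    tukey = pd.concat(tukey_rows, ignore_index=True) if tukey_rows else pd.DataFrame()
    return pd.DataFrame(rows), tukey


def _summarise(metrics: pd.DataFrame, home_ranges: list,
               tests: pd.DataFrame, accuracy: Optional[pd.DataFrame]) -> str:
    lines = ["settrack analysis summary", "=" * 25]
    if not metrics.empty:
        by = metrics.groupby("source")["path_km"]
        lines.append("nightly path length (km): "
                     + "; ".join(f"{s}: {g.mean():.2f} +/- {g.std():.2f}"
                                 for s, g in by))
        if {"gps", "dead_reckoned"} <= set(metrics["source"].unique()):
            ratio = (by.get_group("dead_reckoned").mean()
                     / by.get_group("gps").mean())
            lines.append(f"dead-reckoned / GPS mean path ratio: {ratio:.2f}")
        for cls in ("field", "hedge", "building", "road"):
            col = f"prop_{cls}"
            parts = [f"{s}: {g.mean():.3f}"
                     for s, g in metrics.groupby("source")[col]]
            lines.append(f"proportion of night within 20 m of {cls}: "
                         + "; ".join(parts))
    for hr in home_ranges:
        lines.append(f"home range animal {hr.metadata.get('animal')} "
                     f"{hr.method} ({hr.source}): {hr.area_km2:.3f} km^2")
    if accuracy is not None and not accuracy.empty:
        lines.append(
            f"accuracy vs truth: dead-reckoned RMS "
            f"{accuracy['dr_rms_m'].mean():.1f} m; straight-line GPS "
            f"interpolation RMS {accuracy['gps_interp_rms_m'].mean():.1f} m")
    return "\n".join(lines)


def _homeranges_geojson(home_ranges: list, epsg: int) -> dict:
    from shapely.geometry import mapping
    feats = []
    for hr in home_ranges:
        geom = hr.geometry
        polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        coords = []
        for p in polys:
            rings = [np.asarray(p.exterior.coords)] + \
                    [np.asarray(r.coords) for r in p.interiors]
            out_rings = []
            for ring in rings:
                lat, lon = geo.projected_to_geographic(ring[:, 0], ring[:, 1], epsg)
                out_rings.append([[float(x), float(y)] for x, y in zip(lon, lat)])
            coords.append(out_rings)
        feats.append({
            "type": "Feature",
            "properties": {"method": hr.method, "source": hr.source,
                           "area_km2": hr.area_km2,
                           "animal": hr.metadata.get("animal"),
                           "projected_epsg": epsg,
                           "degenerate": hr.degenerate},
            "geometry": {"type": "MultiPolygon", "coordinates": coords},
        })
    return {"type": "FeatureCollection", "features": feats}


def run_analyse(config: RunConfig, bundle: Optional[SimBundle] = None
                ) -> AnalysisResult:
    """Analyse a study directory (or given bundle) and write the report."""
    out = Path(config.outdir)
    bundle = bundle or load_bundle(config)
    result = analyse_bundle(bundle, config.analysis)

    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "night_metrics.csv", index=False)
    result.tests.to_csv(out / "tests.csv", index=False)
    if not result.tukey.empty:
        result.tukey.to_csv(out / "tukey.csv", index=False)
    if result.accuracy is not None:
        result.accuracy.to_csv(out / "accuracy.csv", index=False)
    with open(out / "home_ranges.geojson", "w") as fh:
        json.dump(_homeranges_geojson(result.home_ranges,
                                      config.analysis.epsg), fh)
    for (a, n), tr in result.dr_tracks.items():
        tr.to_frame().to_csv(out / f"animal{a}_night{n}_dr_track.csv",
                             index=False, float_format="%.3f")
    with open(out / "summary.txt", "w") as fh:
        fh.write(result.summary + "\n")
    return result
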