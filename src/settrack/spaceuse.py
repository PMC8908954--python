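"""Space-use metrics: path length, MCP95/KD95 home ranges, habitat proximity.

Track lengths are summed WGS84 geodesic distances between consecutive
coordinates.  Home ranges follow the standard conventions: the outermost 5%
of locations (by distance from the centroid in the projected frame) are
discarded as outliers/location error, then either the convex hull (MCP95)
or the 95% volume contour of a bivariate Gaussian kernel density (KD95) is
taken.  Habitat proximity counts track points within a 20 m buffer of each
feature class, weighted by dwell time per point: 1/rate seconds for
dead-reckoned samples, one hour per hourly GPS fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, MultiPolygon, Polygon, box
from shapely.ops import unary_union

from . import geo
from .reckon import Track
from .simulate import FEATURE_CLASSES, LandscapeLayer

__all__ = [
    "HomeRange",
    "ProximityBudget",
    "path_length",
    "trim_outliers",
    "mcp_area",
    "kde_home_range",
    "proximity_times",
]


@dataclass
class HomeRange:
    """A home-range polygon set with its area and provenance tags."""

    geometry: Union[Polygon, MultiPolygon]
    area_km2: float
    method: str                       # "MCP95" | "KD95"
    source: str = "unknown"           # "gps" | "dead_reckoned" | "truth"
    trim_fraction: float = 0.05
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_parts(self) -> int:
        if isinstance(self.geometry, MultiPolygon):
            return len(self.geometry.geoms)
        return 0 if self.geometry.is_empty else 1


@dataclass
class ProximityBudget:
    """Per-class time near habitat features for one night and one source.

    Classes are non-exclusive: a position inside a field and within 20 m of
    a hedge counts toward both, so proportions need not sum to 1.
    """

    source: str
    times_s: dict
    proportions: dict
    total_time_s: float
    night: Optional[int] = None
    animal: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_class": list(self.times_s),
            "time_s": [self.times_s[c] for c in self.times_s],
            "proportion": [self.proportions[c] for c in self.times_s],
            "source": self.source, "night": self.night, "animal": self.animal,
        })


def path_length(track: Track) -> float:
    """Total track length in km: summed WGS84 geodesic distances between
    consecutive coordinates."""
    if len(track) < 2:
        return 0.0
    lat, lon = track.lat, track.lon
    d = geo.geodesic_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return float(np.sum(d)) / 1000.0


def trim_outliers(points: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Drop the ``ceil(fraction * n)`` points farthest from the centroid.

    Euclidean distance in the projected frame; ties broken by original
    order (stable sort) so the result is deterministic.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("trim fraction must be in [0, 0.5)")
    points = np.asarray(points, dtype=float)
    n = len(points)
    k = math.ceil(fraction * n)
    if k == 0:
        return points
    centroid = points.mean(axis=0)
    dist = np.linalg.norm(points - centroid, axis=1)
    keep = np.sort(np.argsort(dist, kind="stable")[: n - k])
    return points[keep]


def mcp_area(points: np.ndarray, level: float = 0.95, source: str = "unknown"
             ) -> HomeRange:
    """Minimum convex polygon home range at the given level.

    The outermost ``1 - level`` of locations is trimmed, then the convex
    hull of the remainder is taken; area is reported in km^2.  Collinear or
    degenerate inputs yield a zero-area range with the degenerate flag set.
    """
    points = np.asarray(points, dtype=float)
    trim = 1.0 - level
    kept = trim_outliers(points, trim)
    hull = MultiPoint(kept).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        return HomeRange(geometry=Polygon(), area_km2=0.0, method="MCP95",
                         source=source, trim_fraction=trim, degenerate=True)
    return HomeRange(geometry=hull, area_km2=hull.area / 1e6, method="MCP95",
                     source=source, trim_fraction=trim)


def _mask_to_polygons(mask: np.ndarray, x0: float, y0: float,
                      cell_x: float, cell_y: float) -> Union[Polygon, MultiPolygon]:
    """Union of grid cells where ``mask`` is true (rows = y, cols = x).

    Consecutive cells within a row are merged into single rectangles before
    the union, which keeps the polygon count small.
    """
    boxes = []
    for j in range(mask.shape[0]):
        row = mask[j]
        if not row.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            boxes.append(box(x0 + a * cell_x, y0 + j * cell_y,
                             x0 + b * cell_x, y0 + (j + 1) * cell_y))
    return unary_union(boxes)


def kde_home_range(
    points: np.ndarray,
    level: float = 0.95,
    bandwidth: Union[str, float] = "reference",
    grid_res: int = 200,
    pad_bandwidths: float = 3.0,
    source: str = "unknown",
) -> HomeRange:
    """Kernel utilisation distribution home range (volume contour).

    A bivariate Gaussian kernel density is evaluated on a regular grid
    covering the data extent plus ``pad_bandwidths`` bandwidths, via a 2-D
    histogram smoothed with a Gaussian filter.  The home range is the set
    of cells of highest density whose integrated mass reaches ``level``;
    its polygons and area (km^2) are returned.  The default bandwidth is
    the ad-hoc reference rule ``h = sigma_hat * n**(-1/6)`` with
    ``sigma_hat`` the mean of the marginal standard deviations.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    sd = points.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    if bandwidth == "reference":
        h = float(sd.mean()) * n ** (-1.0 / 6.0)
    else:
        h = float(bandwidth)
    if not np.isfinite(h) or h <= 0 or np.all(sd == 0):
        return HomeRange(geometry=Polygon(), area_km2=0.0, method="KD95",
                         source=source, degenerate=True,
                         metadata={"bandwidth_m": h})

    pad = pad_bandwidths * h
    x0, x1 = points[:, 0].min() - pad, points[:, 0].max() + pad
    y0, y1 = points[:, 1].min() - pad, points[:, 1].max() + pad
    cell_x = (x1 - x0) / grid_res
    cell_y = (y1 - y0) / grid_res
    hist, _, _ = np.histogram2d(
        points[:, 1], points[:, 0], bins=grid_res,
        range=[[y0, y1], [x0, x1]])
    dens = ndimage.gaussian_filter(hist, sigma=(h / cell_y, h / cell_x),
                                   mode="constant")
    total = dens.sum()
    if total <= 0:
        return HomeRange(geometry=Polygon(), area_km2=0.0, method="KD95",
                         source=source, degenerate=True,
                         metadata={"bandwidth_m": h})
    dens /= total

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, level))
    threshold = flat[min(k, len(flat) - 1)]
    mask = dens >= threshold
    mass = float(dens[mask].sum())

    geometry = _mask_to_polygons(mask, x0, y0, cell_x, cell_y)
    area_km2 = int(mask.sum()) * cell_x * cell_y / 1e6
    return HomeRange(
        geometry=geometry, area_km2=area_km2, method="KD95", source=source,
        metadata={"bandwidth_m": h, "grid_res": grid_res,
                  "cell_m": (cell_x, cell_y), "contour_mass": mass})


def proximity_times(
    track: Track,
    landscape: LandscapeLayer,
    radius_m: float = 20.0,
    gps_fix_dwell_s: float = 3600.0,
    night: Optional[int] = None,
) -> ProximityBudget:
    """Time spent within ``radius_m`` of each landscape feature class.

    Buffers are dissolved per class before the point-in-polygon test, so
    overlapping features of one class are not double counted; classes stay
    non-exclusive across classes.  Dead-reckoned (and truth) samples are
    weighted by the sampling interval; each hourly GPS fix stands for
    ``gps_fix_dwell_s`` seconds.
    """
    if track.source == "gps":
        per_point_s = gps_fix_dwell_s
    elif track.source in ("dead_reckoned", "dead_reckoned_unanchored", "truth"):
        if len(track) > 1:
            per_point_s = float(np.median(np.diff(track.t)))
        else:
            per_point_s = 0.0
    else:
        raise ValueError(f"unknown or mixed track source: {track.source!r}")

    total = len(track) * per_point_s
    times: dict = {}
    props: dict = {}
    for cls_name in FEATURE_CLASSES:
        geoms = landscape.by_class(cls_name)
        if not geoms:
            times[cls_name] = 0.0
            props[cls_name] = 0.0
            continue
        buffered = unary_union([g.buffer(radius_m) for g in geoms])
        inside = shapely.contains_xy(buffered, track.easting, track.northing)
        times[cls_name] = float(inside.sum()) * per_point_s
        props[cls_name] = times[cls_name] / total if total > 0 else 0.0
    return ProximityBudget(source=track.source, times_s=times,
                           proportions=props, total_time_s=total,
                           night=night, animal=track.animal)
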