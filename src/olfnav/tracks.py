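"""Per-bird homing indices from GPS tracks.

A released pigeon's track (1 fix / 10 s in the study design) is reduced to
a handful of scalar indices:

* **initial orientation** — circular mean vector of step headings while the
  bird is within 10 km of the release site, and its deviation from west
  (270 degrees); birds with resultant length r < 0.1 did not orient
  consistently and are flagged;
* **HEI**, the homing efficiency index (a/l)·(b−c)/b, where a is the beeline
  release→last fix, l the path length, b the beeline release→home and c the
  beeline last fix→home, all evaluated at the fix reached after 50 min of
  active flight (speed > 10 km/h) or at home arrival if earlier;
* **MAAP**, the mean aggregate azimuth penalty: the mean absolute difference
  between the azimuth required to reach home and the observed azimuth, taken
  at hourly samples along the flight;
* **endpoint distance** — home to the last recorded fix.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import (
    WEST_DEG,
    GeoPoint,
    MeanVector,
    angular_difference,
    bearing_deg,
    circular_mean,
    haversine_distance,
    haversine_km,
    initial_bearing,
)

__all__ = [
    "Track",
    "IndicesConfig",
    "HomingIndices",
    "segment_steps",
    "initial_orientation",
    "homing_efficiency_index",
    "mean_aggregate_azimuth_penalty",
    "compute_indices",
    "indices_table",
]


@dataclass
class Track:
    """One bird's released flight: ordered fixes plus release/home anchors.

    ``fixes`` is a DataFrame with columns ``time`` (datetime64), ``lat``,
    ``lon`` and optionally ``speed_kmh`` (logger-reported speed).
    """

    bird_id: str
    release_site: GeoPoint
    home: GeoPoint
    release_time: pd.Timestamp
    fixes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.bird_id}: needs >= 2 fixes")
        t = self.fixes["time"].to_numpy()
        if not (np.diff(t).astype("timedelta64[ns]") > np.timedelta64(0, "ns")).all():
            raise ValueError(f"track {self.bird_id}: timestamps not strictly increasing")
        self.release_time = pd.Timestamp(self.release_time)
        if self.release_time > pd.Timestamp(t[0]):
            raise ValueError(f"track {self.bird_id}: release_time after first fix")

    @property
    def has_logger_speed(self) -> bool:
        return "speed_kmh" in self.fixes.columns and self.fixes["speed_kmh"].notna().all()


@dataclass
class IndicesConfig:
    """Knobs for the index computations; defaults follow the study design."""

    radius_km: float = 10.0           # initial-orientation window around release
    active_minutes: float = 50.0      # active-flight clock for HEI truncation
    speed_threshold_kmh: float = 10.0  # "active flight" speed cut
    home_radius_km: float = 0.5       # "reached home" radius
    signed_west: bool = True          # deviation-from-west convention
    r_threshold: float = 0.1          # consistency cut on the mean vector
    maap_interval_s: float = 3600.0
    maap_tolerance_s: float = 300.0   # nearest-fix window around each boundary
    orientation_mode: str = "step_headings"  # or "bearing_from_release"


@dataclass
class HomingIndices:
    bird_id: str
    mean_vector: MeanVector
    deviation_from_west: float
    consistent: bool
    hei: float
    maap: float
    endpoint_distance_km: float

    def as_row(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "mean_direction_deg": self.mean_vector.direction,
            "r": self.mean_vector.r,
            "consistent": self.consistent,
            "deviation_from_west": self.deviation_from_west,
            "deviation_from_west_abs": abs(self.deviation_from_west)
            if math.isfinite(self.deviation_from_west)
            else math.nan,
            "hei": self.hei,
            "maap": self.maap,
            "endpoint_distance_km": self.endpoint_distance_km,
        }


def segment_steps(track: Track) -> pd.DataFrame:
    """Per consecutive-fix step table.

    Columns: ``heading_deg`` (NaN for zero-length steps, which are excluded
    from all heading statistics), ``length_km``, ``duration_s``, ``speed_kmh``
    (logger speed of the starting fix when recorded, else length/duration),
    ``start_dist_release_km`` and ``zero_length``.
    """
    f = track.fixes
    lat = f["lat"].to_numpy(dtype=float)
    lon = f["lon"].to_numpy(dtype=float)
    t = f["time"].to_numpy()
    duration = np.diff(t).astype("timedelta64[ns]").astype(float) / 1e9
    length = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    zero = length <= 0.0
    heading = bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    heading = np.where(zero, np.nan, heading)
    with np.errstate(divide="ignore", invalid="ignore"):
        derived_speed = np.where(duration > 0, length / duration * 3600.0, np.nan)
    if track.has_logger_speed:
        speed = f["speed_kmh"].to_numpy(dtype=float)[:-1]
    else:
        speed = derived_speed
    start_dist = haversine_km(track.release_site.lat, track.release_site.lon, lat[:-1], lon[:-1])
    return pd.DataFrame(
        {
            "heading_deg": heading,
            "length_km": np.asarray(length, dtype=float),
            "duration_s": duration,
            "speed_kmh": speed,
            "start_dist_release_km": np.asarray(start_dist, dtype=float),
            "zero_length": zero,
        }
    )


def initial_orientation(
    track: Track,
    radius_km: float = 10.0,
    mode: str = "step_headings",
    steps: Optional[pd.DataFrame] = None,
) -> MeanVector:
    """Unweighted circular mean of the bird's headings near the release site.

    ``mode="step_headings"`` (default) averages the headings of steps whose
    starting fix lies within ``radius_km`` of the release site;
    ``mode="bearing_from_release"`` instead averages the bearings from the
    release site to each fix in that window.
    """
    if steps is None:
        steps = segment_steps(track)
    within = steps["start_dist_release_km"].to_numpy() <= radius_km
    if mode == "step_headings":
        angles = steps.loc[within & ~steps["zero_length"], "heading_deg"].to_numpy()
    elif mode == "bearing_from_release":
        f = track.fixes.iloc[1:]  # skip the release fix itself
        lat = f["lat"].to_numpy(dtype=float)
        lon = f["lon"].to_numpy(dtype=float)
        d = haversine_km(track.release_site.lat, track.release_site.lon, lat, lon)
        sel = (d <= radius_km) & (d > 0)
        angles = bearing_deg(track.release_site.lat, track.release_site.lon, lat[sel], lon[sel])
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    if np.size(angles) == 0:
        raise ValueError(f"track {track.bird_id}: no qualifying steps within {radius_km} km")
    return circular_mean(angles)


def _truncation_index(
    track: Track, steps: pd.DataFrame, active_minutes: float,
    speed_threshold_kmh: float, home_radius_km: float,
) -> int:
    """Index (into fixes) of the HEI truncation fix.

    The clock accumulates only active-flight time (speed above threshold);
    truncation happens at the first fix where the clock reaches the limit,
    or earlier at home arrival, or at the last fix if neither occurs.
    """
    active = steps["speed_kmh"].to_numpy() > speed_threshold_kmh
    cum_active = np.concatenate([[0.0], np.cumsum(steps["duration_s"].to_numpy() * active)])
    n = len(track.fixes)
    limit = active_minutes * 60.0
    hit = np.nonzero(cum_active >= limit)[0]
    idx_time = int(hit[0]) if hit.size else n - 1
    lat = track.fixes["lat"].to_numpy(dtype=float)
    lon = track.fixes["lon"].to_numpy(dtype=float)
    home_dist = haversine_km(track.home.lat, track.home.lon, lat, lon)
    arrived = np.nonzero(home_dist[1:] <= home_radius_km)[0]
    idx_home = int(arrived[0]) + 1 if arrived.size else n - 1
    return min(idx_time, idx_home)


def homing_efficiency_index(
    track: Track,
    active_minutes: float = 50.0,
    speed_threshold_kmh: float = 10.0,
    home_radius_km: float = 0.5,
    steps: Optional[pd.DataFrame] = None,
    return_components: bool = False,
):
    """HEI = (a/l)·(b−c)/b on the track truncated by the active-flight clock.

    ``l`` sums ALL step lengths up to the truncation fix (the activity cut
    gates only the clock, not the path length). Positive values mean net
    approach to home; a bird flying straight away from home scores negative.
    """
    if steps is None:
        steps = segment_steps(track)
    b = haversine_distance(track.release_site, track.home)
    if b <= 0:
        raise ValueError("release site coincides with home: b = 0")
    idx = _truncation_index(track, steps, active_minutes, speed_threshold_kmh, home_radius_km)
    if idx < 1:
        raise ValueError("truncated track has no steps")
    fix = track.fixes.iloc[idx]
    end = GeoPoint(float(fix["lat"]), float(fix["lon"]))
    a = haversine_distance(track.release_site, end)
    l = float(steps["length_km"].to_numpy()[:idx].sum())
    c = haversine_distance(end, track.home)
    if l <= 0:
        raise ValueError("zero track length up to truncation")
    hei = (a / l) * (b - c) / b
    if return_components:
        return hei, {"a": a, "l": l, "b": b, "c": c, "truncation_index": idx}
    return hei


def mean_aggregate_azimuth_penalty(
    track: Track,
    interval_s: float = 3600.0,
    tolerance_s: float = 300.0,
) -> float:
    """Mean absolute difference between required and observed azimuths.

    The flight is downsampled to one fix per ``interval_s`` (nearest fix
    within ``tolerance_s`` of each boundary; boundaries with no fix — signal
    loss — are skipped and not penalised). At each retained sample the
    required azimuth A points from the sample to home and the observed
    azimuth is the displacement bearing to the next retained sample; the
    result is the mean of |A − observed| in [0, 180].
    """
    times = track.fixes["time"].to_numpy().astype("datetime64[ns]").astype("int64") / 1e9
    t0 = pd.Timestamp(track.release_time).as_unit("ns").value / 1e9
    n_bounds = int(math.floor((times[-1] - t0) / interval_s)) + 1
    sample_idx: list[int] = []
    for k in range(n_bounds):
        target = t0 + k * interval_s
        i = int(np.argmin(np.abs(times - target)))
        if abs(times[i] - target) <= tolerance_s:
            if not sample_idx or sample_idx[-1] != i:
                sample_idx.append(i)
    if len(sample_idx) < 2:
        raise ValueError(f"track {track.bird_id}: fewer than 2 hourly samples for MAAP")
    lat = track.fixes["lat"].to_numpy(dtype=float)
    lon = track.fixes["lon"].to_numpy(dtype=float)
    devs = []
    for i, j in zip(sample_idx[:-1], sample_idx[1:]):
        if lat[i] == lat[j] and lon[i] == lon[j]:
            continue  # no displacement: no observed azimuth for this interval
        required = bearing_deg(lat[i], lon[i], track.home.lat, track.home.lon)
        observed = bearing_deg(lat[i], lon[i], lat[j], lon[j])
        devs.append(angular_difference(required, observed))
    if not devs:
        raise ValueError(f"track {track.bird_id}: no displaced hourly samples for MAAP")
    return float(np.mean(devs))


def compute_indices(track: Track, config: Optional[IndicesConfig] = None) -> HomingIndices:
    """All per-bird indices; components that cannot be evaluated are NaN.

    Birds whose initial mean vector has r below the consistency threshold
    keep their indices but are flagged ``consistent=False`` (downstream
    association analyses exclude them).
    """
    cfg = config or IndicesConfig()
    steps = segment_steps(track)
    try:
        mv = initial_orientation(track, cfg.radius_km, cfg.orientation_mode, steps=steps)
    except ValueError:
        mv = MeanVector(direction=math.nan, r=0.0)
    if mv.defined:
        dev = angular_difference(mv.direction, WEST_DEG, signed=cfg.signed_west)
    else:
        dev = math.nan
    try:
        hei = homing_efficiency_index(
            track, cfg.active_minutes, cfg.speed_threshold_kmh, cfg.home_radius_km, steps=steps
        )
    except ValueError:
        hei = math.nan
    try:
        maap = mean_aggregate_azimuth_penalty(track, cfg.maap_interval_s, cfg.maap_tolerance_s)
    except ValueError:
        maap = math.nan
    last = track.fixes.iloc[-1]
    endpoint = haversine_distance(GeoPoint(float(last["lat"]), float(last["lon"])), track.home)
    return HomingIndices(
        bird_id=track.bird_id,
        mean_vector=mv,
        deviation_from_west=float(dev),
        consistent=bool(mv.defined and mv.r >= cfg.r_threshold),
        hei=float(hei),
        maap=float(maap),
        endpoint_distance_km=endpoint,
    )


def indices_table(tracks: Sequence[Track], config: Optional[IndicesConfig] = None) -> pd.DataFrame:
    """One row of indices per bird."""
    rows = [compute_indices(t, config).as_row() for t in tracks]
    return pd.DataFrame(rows)
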