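"""Air-mass trajectories, land/sea residence accounting and the west wind component.

Consumes HYSPLIT trajectory endpoint ("tdump") files with the MIXDEPTH
diagnostic, classifies each hourly parcel position as marine boundary layer,
land boundary layer or above the boundary layer, and summarises wind-profile
occupancy matrices into the scalar west wind component

    WWC = sum_ij cos(theta_i) * S_j * P_ij

over 16 directions (theta = 0 aligned with west, pi with east) and 6 ordinal
speed classes.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape, mapping, box

from .geo import GeoPoint

__all__ = [
    "TrajectoryPoint",
    "Trajectory",
    "ResidenceCounts",
    "WindProfile",
    "HalfPlaneMask",
    "PolygonMask",
    "MaskCoverageError",
    "parse_hysplit_endpoints",
    "write_hysplit_endpoints",
    "classify_trajectory",
    "build_wind_profile",
    "west_wind_component",
    "DEFAULT_SPEED_EDGES",
]

#: default speed-class edges (m/s) for the 16 x 6 occupancy matrix
DEFAULT_SPEED_EDGES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, math.inf)


class MaskCoverageError(ValueError):
    """A trajectory point fell outside the land/sea mask coverage."""


@dataclass(frozen=True)
class TrajectoryPoint:
    hour_offset: int          # hours relative to release; negative = backward
    pos: GeoPoint
    altitude_m: float         # above ground
    mixing_depth_m: float

    def __post_init__(self) -> None:
        if self.mixing_depth_m <= 0:
            raise ValueError("mixing depth must be positive")
        if self.altitude_m < 0:
            raise ValueError("altitude must be non-negative")


@dataclass
class Trajectory:
    """24 h of hourly air-parcel positions from one release site and time."""

    site: GeoPoint
    start_time: datetime
    direction: str  # "backward" | "forward"
    points: list[TrajectoryPoint] = field(repr=False)

    def __post_init__(self) -> None:
        if self.direction not in ("backward", "forward"):
            raise ValueError(f"direction must be backward/forward, got {self.direction!r}")
        offs = [p.hour_offset for p in self.points]
        if len(offs) > 25 or any(abs(o) > 24 for o in offs):
            raise ValueError("at most 25 hourly points within +-24 h")
        if any(b - a != (1 if self.direction == "forward" else -1) for a, b in zip(offs, offs[1:])):
            raise ValueError("hour offsets must be consecutive")


@dataclass(frozen=True)
class ResidenceCounts:
    """Hours the parcel spent in each of the three transport classes.

    Ratios use x/0 = +inf (rank statistics downstream handle infinities);
    0/0 is NaN (the whole window above the boundary layer).
    """

    hours_sea_bl: float
    hours_land_bl: float
    hours_above_bl: float

    @property
    def window_h(self) -> float:
        return self.hours_sea_bl + self.hours_land_bl + self.hours_above_bl

    @property
    def ratio_sea_land(self) -> float:
        return _safe_ratio(self.hours_sea_bl, self.hours_land_bl)

    @property
    def ratio_land_sea(self) -> float:
        return _safe_ratio(self.hours_land_bl, self.hours_sea_bl)

    def as_row(self) -> dict:
        return {
            "hours_sea_bl": self.hours_sea_bl,
            "hours_land_bl": self.hours_land_bl,
            "hours_above_bl": self.hours_above_bl,
            "ratio_sea_land": self.ratio_sea_land,
            "ratio_land_sea": self.ratio_land_sea,
        }


def _safe_ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


# ---------------------------------------------------------------------------
# land / sea masks

class HalfPlaneMask:
    """Idealised straight coastline: sea wherever lon < coast_lon."""

    def __init__(self, coast_lon: float):
        self.coast_lon = float(coast_lon)

    def is_sea(self, lat: float, lon: float) -> bool:
        return lon < self.coast_lon

    def to_geojson(self, path) -> None:
        """Write the half-plane as a two-polygon GeoJSON mask."""
        sea = box(-179.999, -85.0, self.coast_lon, 85.0)
        land = box(self.coast_lon, -85.0, 179.999, 85.0)
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"surface": "sea"}, "geometry": mapping(sea)},
                {"type": "Feature", "properties": {"surface": "land"}, "geometry": mapping(land)},
            ],
        }
        with open(path, "w") as fh:
            json.dump(fc, fh)


class PolygonMask:
    """Land/sea mask from polygon sets (e.g. a GeoJSON coastline).

    If only sea polygons are given, everything else is land. If land
    polygons are also given, a point in neither raises
    :class:`MaskCoverageError`.
    """

    def __init__(self, sea_geoms: Sequence, land_geoms: Optional[Sequence] = None):
        self.sea_geoms = list(sea_geoms)
        self.land_geoms = list(land_geoms) if land_geoms is not None else None

    @classmethod
    def from_geojson(cls, path) -> "PolygonMask":
        with open(path) as fh:
            fc = json.load(fh)
        sea, land = [], []
        for feat in fc.get("features", []):
            surface = feat.get("properties", {}).get("surface")
            geom = shape(feat["geometry"])
            if surface == "sea":
                sea.append(geom)
            elif surface == "land":
                land.append(geom)
        if not sea:
            raise ValueError("mask file defines no sea polygons")
        return cls(sea, land or None)

    def is_sea(self, lat: float, lon: float) -> bool:
        pt = Point(lon, lat)
        if any(g.covers(pt) for g in self.sea_geoms):
            return True
        if self.land_geoms is not None and not any(g.covers(pt) for g in self.land_geoms):
            raise MaskCoverageError(f"point ({lat}, {lon}) outside mask coverage")
        return False


# ---------------------------------------------------------------------------
# HYSPLIT endpoint files

def parse_hysplit_endpoints(path) -> list[Trajectory]:
    """Parse a HYSPLIT trajectory endpoint (tdump) file.

    Expects the standard layout: met-grid header block, trajectory start
    block, a diagnostics line that must include MIXDEPTH, then one row per
    trajectory-hour with columns traj#, grid#, yr, mo, da, hr, mn,
    forecast-hour, age, lat, lon, height, diagnostics...
    """
    with open(path) as fh:
        lines = fh.readlines()
    lineno = 0

    def next_tokens():
        nonlocal lineno
        while lineno < len(lines):
            toks = lines[lineno].split()
            lineno += 1
            if toks:
                return toks, lineno
        raise ValueError(f"{path}: unexpected end of file at line {lineno}")

    toks, ln = next_tokens()
    try:
        n_grids = int(toks[0])
    except ValueError as exc:
        raise ValueError(f"{path}:{ln}: bad met-grid count") from exc
    for _ in range(n_grids):
        next_tokens()
    toks, ln = next_tokens()
    n_traj = int(toks[0])
    direction = toks[1].lower() if len(toks) > 1 else "backward"
    starts = []
    for _ in range(n_traj):
        toks, ln = next_tokens()
        try:
            yr, mo, da, hr = (int(float(v)) for v in toks[:4])
            lat, lon, height = (float(v) for v in toks[4:7])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: malformed trajectory start line") from exc
        starts.append((datetime(yr + 2000 if yr < 100 else yr, mo, da, hr), lat, lon, height))
    toks, ln = next_tokens()
    n_diag = int(toks[0])
    diag_names = [t.upper() for t in toks[1 : 1 + n_diag]]
    if "MIXDEPTH" not in diag_names:
        raise ValueError(
            f"{path}: MIXDEPTH diagnostic missing (found {diag_names or 'none'}); "
            "request mixing-layer depth output when running HYSPLIT"
        )
    mix_col = 12 + diag_names.index("MIXDEPTH")

    rows: dict[int, list[TrajectoryPoint]] = {i + 1: [] for i in range(n_traj)}
    while lineno < len(lines):
        toks = lines[lineno].split()
        lineno += 1
        if not toks:
            continue
        try:
            tn = int(toks[0])
            age = float(toks[8])
            lat, lon, height = float(toks[9]), float(toks[10]), float(toks[11])
            mixdepth = float(toks[mix_col])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed endpoint row") from exc
        rows[tn].append(
            TrajectoryPoint(int(round(age)), GeoPoint(lat, lon), height, mixdepth)
        )
    out = []
    for i, (start, lat, lon, _h) in enumerate(starts, start=1):
        pts = sorted(rows[i], key=lambda p: p.hour_offset, reverse=(direction == "backward"))
        out.append(Trajectory(GeoPoint(lat, lon), start, direction, pts))
    return out


def write_hysplit_endpoints(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories in the tdump dialect read back by the parser."""
    if not trajectories:
        raise ValueError("no trajectories to write")
    direction = trajectories[0].direction
    with open(path, "w") as fh:
        fh.write("     1     1\n")
        fh.write("    SYNT    16     1     1     0     0\n")
        fh.write(f"{len(trajectories):6d} {direction.upper()} OMEGA\n")
        for tr in trajectories:
            st = tr.start_time
            fh.write(
                f"{st.year % 100:6d}{st.month:6d}{st.day:6d}{st.hour:6d}"
                f"{tr.site.lat:9.3f}{tr.site.lon:9.3f}{150.0:9.1f}\n"
            )
        fh.write("     2 PRESSURE MIXDEPTH\n")
        for i, tr in enumerate(trajectories, start=1):
            st = tr.start_time
            for p in tr.points:
                fh.write(
                    f"{i:6d}{1:6d}{st.year % 100:6d}{st.month:6d}{st.day:6d}"
                    f"{st.hour:6d}{0:6d}{0:6d}{float(p.hour_offset):8.1f}"
                    f"{p.pos.lat:9.3f}{p.pos.lon:9.3f}{p.altitude_m:9.1f}"
                    f"{900.0:9.1f}{p.mixing_depth_m:9.1f}\n"
                )


# ---------------------------------------------------------------------------
# residence classification

def classify_trajectory(traj: Trajectory, mask, window_h: int = 24) -> ResidenceCounts:
    """Count hours in marine BL / land BL / above BL over the analysis window.

    For backward trajectories the window is the ``window_h`` hours prior to
    release (offsets -window_h .. -1); for forward, offsets 1 .. window_h.
    The origin point contributes nothing. Above-BL (altitude above the local
    mixing depth) takes precedence over the surface classes.
    """
    if traj.direction == "backward":
        wanted = set(range(-window_h, 0))
    else:
        wanted = set(range(1, window_h + 1))
    sea = land = above = 0.0
    seen = 0
    for p in traj.points:
        if p.hour_offset not in wanted:
            continue
        seen += 1
        if p.altitude_m > p.mixing_depth_m:
            above += 1.0
        elif mask.is_sea(p.pos.lat, p.pos.lon):
            sea += 1.0
        else:
            land += 1.0
    if seen < window_h:
        raise ValueError(
            f"trajectory spans only {seen} of the requested {window_h} window hours"
        )
    return ResidenceCounts(sea, land, above)


def residence_table(trajectories: Iterable[tuple[str, Trajectory]], mask, window_h: int = 24) -> pd.DataFrame:
    """Residence counts keyed by an identifier (e.g. bird_id)."""
    rows = []
    for key, tr in trajectories:
        row = {"bird_id": key}
        row.update(classify_trajectory(tr, mask, window_h).as_row())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wind profiles and the west wind component

@dataclass
class WindProfile:
    """16-direction x 6-speed-class occupancy matrix.

    ``theta`` holds the 16 encoded angles i*pi/8 with 0 aligned to west and
    pi to east; ``S`` is the speed-class weight vector (ordinal ranks 1..6
    by default, or physical class midpoints); ``P`` the time-fraction matrix.
    """

    theta: np.ndarray
    S: np.ndarray
    P: np.ndarray
    speed_edges: tuple = DEFAULT_SPEED_EDGES

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.theta), len(self.S)):
            raise ValueError(f"P shape {self.P.shape} does not match theta x S")
        if (self.P < 0).any():
            raise ValueError("P entries must be non-negative")
        if not math.isclose(float(self.P.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"P must sum to 1 (got {self.P.sum()})")


def compass_to_theta_deg(wd_deg):
    """Map meteorological coming-from compass degrees to the theta encoding
    (0 = west, 180 = east), degrees in [0, 360)."""
    return (270.0 - np.asarray(wd_deg, dtype=float)) % 360.0


def build_wind_profile(
    wd_deg=None,
    ws_ms=None,
    *,
    met: Optional[pd.DataFrame] = None,
    n_dirs: int = 16,
    speed_edges: Sequence[float] = DEFAULT_SPEED_EDGES,
    s_values: str | Sequence[float] = "ordinal",
) -> WindProfile:
    """Bin a wind record into the 16 x 6 occupancy matrix.

    Directions are meteorological coming-from compass degrees; sectors are
    centred on the 16 encoded angles (compass 270 falls in the theta = 0
    sector). ``s_values`` is ``"ordinal"`` (ranks 1..6), ``"midpoint"``
    (speed-class midpoints in m/s, the open last class using its lower edge),
    or an explicit 6-vector.
    """
    if met is not None:
        wd_deg = met["wd_deg"].to_numpy(dtype=float)
        ws_ms = met["ws_ms"].to_numpy(dtype=float)
    wd = np.asarray(wd_deg, dtype=float)
    ws = np.asarray(ws_ms, dtype=float)
    if wd.size == 0:
        raise ValueError("empty wind record")
    if (ws < 0).any():
        raise ValueError("wind speeds must be non-negative")
    edges = np.asarray(speed_edges, dtype=float)
    if len(edges) != 7 or (np.diff(edges) <= 0).any():
        raise ValueError("speed_edges must be 7 strictly increasing values (6 classes)")
    sector_width = 360.0 / n_dirs
    sector = np.round(compass_to_theta_deg(wd) / sector_width).astype(int) % n_dirs
    cls = np.clip(np.searchsorted(edges, ws, side="right") - 1, 0, 5)
    P = np.zeros((n_dirs, 6))
    np.add.at(P, (sector, cls), 1.0)
    P /= P.sum()
    if isinstance(s_values, str):
        if s_values == "ordinal":
            S = np.arange(1.0, 7.0)
        elif s_values == "midpoint":
            mids = (edges[:-1] + edges[1:]) / 2.0
            if not np.isfinite(mids[-1]):
                mids[-1] = edges[-2]
            S = mids
        else:
            raise ValueError(f"unknown s_values {s_values!r}")
    else:
        S = np.asarray(s_values, dtype=float)
        if S.shape != (6,):
            raise ValueError("explicit s_values must have length 6")
    theta = np.arange(n_dirs) * (2.0 * math.pi / n_dirs)
    return WindProfile(theta=theta, S=S, P=P, speed_edges=tuple(edges))


def west_wind_component(profile: WindProfile) -> float:
    """WWC = sum_ij cos(theta_i) * S_j * P_ij.

    Positive when the occupancy mass sits in the western hemisphere (winds
    coming from westerly compass sectors), negative for easterly regimes;
    bounded by +-max(S).
    """
    return float(np.cos(profile.theta) @ profile.P @ profile.S)


# CSV round trip for profiles -------------------------------------------------

def wind_profile_to_csv(profile: WindProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# speed_edges=" + ",".join(str(e) for e in profile.speed_edges) + "\n")
        fh.write("# s_values=" + ",".join(str(v) for v in profile.S) + "\n")
        df = pd.DataFrame(
            profile.P,
            index=pd.Index(np.degrees(profile.theta), name="theta_deg"),
            columns=[f"class_{j + 1}" for j in range(6)],
        )
        df.to_csv(fh)


def wind_profile_from_csv(path) -> WindProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = [float(v) for v in val.split(",")]
    df = pd.read_csv(path, comment="#", index_col="theta_deg")
    P = df.to_numpy(dtype=float)
    return WindProfile(
        theta=np.radians(df.index.to_numpy(dtype=float)),
        S=np.asarray(meta.get("s_values", np.arange(1.0, 7.0))),
        P=P / P.sum(),
        speed_edges=tuple(meta.get("speed_edges", DEFAULT_SPEED_EDGES)),
    )
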