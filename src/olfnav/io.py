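"""CSV readers and writers shared across the command-line subcommands.

Formats (all plain CSV, ISO-8601 timestamps):

* tracks:   bird_id, time, lat, lon[, speed_kmh] — one row per GPS fix
* sites:    bird_id, release_lat, release_lon, home_lat, home_lon, release_time
* met:      time, temp_c, rh_pct, ws_ms, wd_deg, rain_mm
* voc:      time, species, vmr_ppbv (long format)
* indices / residence / association: one row per bird / analysis
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from .geo import GeoPoint
from .tracks import Track
from .voc import VOCTimeSeries


def read_tracks_csv(tracks_path, sites_path) -> list[Track]:
    """Assemble Track objects from a fixes file and a companion sites file."""
    fixes = pd.read_csv(tracks_path, parse_dates=["time"])
    sites = pd.read_csv(sites_path, parse_dates=["release_time"]).set_index("bird_id")
    tracks = []
    for bird_id, grp in fixes.groupby("bird_id", sort=False):
        if bird_id not in sites.index:
            raise ValueError(f"bird {bird_id!r} missing from sites file")
        s = sites.loc[bird_id]
        cols = ["time", "lat", "lon"] + (["speed_kmh"] if "speed_kmh" in grp.columns else [])
        tracks.append(
            Track(
                bird_id=str(bird_id),
                release_site=GeoPoint(float(s["release_lat"]), float(s["release_lon"])),
                home=GeoPoint(float(s["home_lat"]), float(s["home_lon"])),
                release_time=pd.Timestamp(s["release_time"]),
                fixes=grp[cols].sort_values("time").reset_index(drop=True),
            )
        )
    if not tracks:
        raise ValueError(f"no tracks found in {tracks_path}")
    return tracks


def write_tracks_csv(tracks: Sequence[Track], tracks_path, sites_path) -> None:
    fix_frames, site_rows = [], []
    for t in tracks:
        f = t.fixes.copy()
        f.insert(0, "bird_id", t.bird_id)
        fix_frames.append(f)
        site_rows.append(
            {
                "bird_id": t.bird_id,
                "release_lat": t.release_site.lat,
                "release_lon": t.release_site.lon,
                "home_lat": t.home.lat,
                "home_lon": t.home.lon,
                "release_time": t.release_time,
            }
        )
    pd.concat(fix_frames, ignore_index=True).to_csv(tracks_path, index=False)
    pd.DataFrame(site_rows).to_csv(sites_path, index=False)


def read_met_csv(path) -> pd.DataFrame:
    met = pd.read_csv(path, parse_dates=["time"])
    required = {"time", "ws_ms", "wd_deg"}
    missing = required - set(met.columns)
    if missing:
        raise ValueError(f"met file missing columns: {sorted(missing)}")
    return met


def read_voc_csv(path, tz_offset_h: float = 0.0) -> list[VOCTimeSeries]:
    df = pd.read_csv(path, parse_dates=["time"])
    return [
        VOCTimeSeries(
            species=str(sp),
            data=grp[["time", "vmr_ppbv"]].sort_values("time").reset_index(drop=True),
            tz_offset_h=tz_offset_h,
        )
        for sp, grp in df.groupby("species", sort=False)
    ]


def write_voc_csv(series_list: Sequence[VOCTimeSeries], path) -> None:
    frames = []
    for s in series_list:
        f = s.data.copy()
        f.insert(0, "species", s.species)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
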