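import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from olfnav.geo import GeoPoint, destination_point

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def home() -> GeoPoint:
    """The coastal home aviary used throughout the synthetic scenario."""
    return GeoPoint(43.6572, 10.3039)


@pytest.fixture
def release_site(home) -> GeoPoint:
    """Release site 61 degrees / 59.9 km from home (home azimuth 241)."""
    return destination_point(home, 61.0, 59.9)


def straight_track_fixes(start: GeoPoint, bearing: float, speed_kmh: float,
                         n_fixes: int, step_s: float = 10.0,
                         t0: str = "2016-07-04T08:00:00") -> pd.DataFrame:
    """Fixes marching along one great circle at constant speed."""
    pts = [start]
    step_km = speed_kmh * step_s / 3600.0
    for _ in range(n_fixes - 1):
        pts.append(destination_point(pts[-1], bearing, step_km))
    times = pd.Timestamp(t0) + pd.to_timedelta(np.arange(n_fixes) * step_s, unit="s")
    return pd.DataFrame(
        {"time": times, "lat": [p.lat for p in pts], "lon": [p.lon for p in pts]}
    )


def aimed_track_fixes(start: GeoPoint, target: GeoPoint, speed_kmh: float,
                      n_fixes: int, step_s: float = 10.0,
                      bearing_offset: float = 0.0,
                      stop_at_target: bool = False,
                      t0: str = "2016-07-04T08:00:00") -> pd.DataFrame:
    """Fixes re-aiming at ``target`` (plus a constant bearing offset) each step.

    With zero offset this traces the great circle toward the target; a 90
    degree offset circles it at constant range error. ``stop_at_target``
    makes the last fix coincide exactly with the target.
    """
    from olfnav.geo import haversine_distance, initial_bearing

    pts = [start]
    step_km = speed_kmh * step_s / 3600.0
    for _ in range(n_fixes - 1):
        if stop_at_target and haversine_distance(pts[-1], target) <= step_km:
            pts.append(target)
            break
        b = (initial_bearing(pts[-1], target) + bearing_offset) % 360.0
        pts.append(destination_point(pts[-1], b, step_km))
    n_fixes = len(pts)
    times = pd.Timestamp(t0) + pd.to_timedelta(np.arange(n_fixes) * step_s, unit="s")
    return pd.DataFrame(
        {"time": times, "lat": [p.lat for p in pts], "lon": [p.lon for p in pts]}
    )
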