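"""VOC time-series processing: background subtraction, diel cycles,
bivariate polar maps and atmospheric-lifetime arithmetic.

A species' navigational usefulness hinges on how far it survives transport:
with OH as the dominant daytime oxidant its lifetime is tau = 1/(k_OH [OH])
and the horizontal e-folding range at wind speed u is simply u*tau. Species
with tau of hours maintain regional (tens of km) gradients; very reactive
ones fade within a few km of their source.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VOCTimeSeries",
    "BackgroundRun",
    "DielCycle",
    "PolarGrid",
    "LifetimeSpec",
    "subtract_background",
    "diel_cycle",
    "polar_bin",
    "oh_lifetime",
    "efolding_distance",
    "load_rate_constants",
    "lifetime_table",
    "DEFAULT_OH_CONC",
    "DEFAULT_WIND_SPEED_MS",
]

#: campaign-typical OH radical concentration, molecules cm^-3
DEFAULT_OH_CONC = 2.0e6
#: typical regional transport wind speed, m/s
DEFAULT_WIND_SPEED_MS = 2.2


@dataclass
class VOCTimeSeries:
    """Mixing-ratio record for one species (name and/or PTR-MS m/z label).

    ``data`` has columns ``time`` (datetime64, increasing) and ``vmr_ppbv``.
    ``tz_offset_h`` converts the (UTC) timestamps to local time for diel
    statistics. ``clipped_count`` records values clipped to zero by
    background subtraction.
    """

    species: str
    data: pd.DataFrame = field(repr=False)
    tz_offset_h: float = 0.0
    clipped_count: int = 0

    def __post_init__(self) -> None:
        t = self.data["time"].to_numpy()
        if len(t) and not (np.diff(t).astype("timedelta64[ns]") >= np.timedelta64(0, "ns")).all():
            raise ValueError(f"{self.species}: timestamps must be increasing")

    def local_times(self) -> pd.Series:
        return self.data["time"] + pd.to_timedelta(self.tz_offset_h, unit="h")


@dataclass(frozen=True)
class BackgroundRun:
    """One zero-air background measurement period and its mean signal."""

    start: pd.Timestamp
    end: pd.Timestamp
    level_ppbv: float

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("background run must have positive duration")

    @property
    def midpoint(self) -> pd.Timestamp:
        return pd.Timestamp(self.start) + (pd.Timestamp(self.end) - pd.Timestamp(self.start)) / 2


def subtract_background(series: VOCTimeSeries, backgrounds: Sequence[BackgroundRun]) -> VOCTimeSeries:
    """Subtract instrument background, linearly interpolated between runs.

    The background level is anchored at each run's midpoint, interpolated
    linearly in time between midpoints and held constant before the first /
    after the last run. Ambient values that go negative after subtraction
    are clipped to zero and counted in ``clipped_count``.
    """
    if not backgrounds:
        raise ValueError("at least one background run required")
    runs = sorted(backgrounds, key=lambda b: b.midpoint)
    anchors = np.array([b.midpoint.value for b in runs], dtype=float)
    levels = np.array([b.level_ppbv for b in runs], dtype=float)
    t = series.data["time"].to_numpy().astype("datetime64[ns]").astype("int64").astype(float)
    bg = np.interp(t, anchors, levels)
    vmr = series.data["vmr_ppbv"].to_numpy(dtype=float) - bg
    clipped = int((vmr < 0).sum())
    out = series.data.copy()
    out["vmr_ppbv"] = np.clip(vmr, 0.0, None)
    return replace(series, data=out, clipped_count=series.clipped_count + clipped)


# ---------------------------------------------------------------------------
# diel cycles

@dataclass
class DielCycle:
    """Hour-of-day statistics of a mixing-ratio record.

    Statistics are taken across *days* on within-day hourly means (each
    calendar day contributes one value per local hour), matching the
    campaign convention of reporting a maximum hourly average +- 1 sd.
    ``stats`` is indexed by local hour 0..23 with columns mean, median,
    q25, q75, p10, p90, sd and n_days; hours never observed are NaN.
    """

    species: str
    stats: pd.DataFrame = field(repr=False)
    peak_hour: int = 0
    max_hourly_mean: float = math.nan
    sd_at_peak: float = math.nan


def diel_cycle(series: VOCTimeSeries) -> DielCycle:
    if series.data.empty:
        raise ValueError(f"{series.species}: empty series")
    local = series.local_times()
    df = pd.DataFrame(
        {
            "day": local.dt.normalize().to_numpy(),
            "hour": local.dt.hour.to_numpy(),
            "vmr": series.data["vmr_ppbv"].to_numpy(dtype=float),
        }
    )
    hourly = df.groupby(["day", "hour"], sort=True)["vmr"].mean().reset_index()
    g = hourly.groupby("hour")["vmr"]
    stats = pd.DataFrame(
        {
            "mean": g.mean(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
            "p10": g.quantile(0.10),
            "p90": g.quantile(0.90),
            "sd": g.std(ddof=1),
            "n_days": g.count(),
        }
    ).reindex(range(24))
    stats.index.name = "hour"
    peak = int(stats["mean"].idxmax())
    return DielCycle(
        species=series.species,
        stats=stats,
        peak_hour=peak,
        max_hourly_mean=float(stats.loc[peak, "mean"]),
        sd_at_peak=float(stats.loc[peak, "sd"]),
    )


# ---------------------------------------------------------------------------
# bivariate polar maps

@dataclass
class PolarGrid:
    """Mean mixing ratio binned jointly by wind direction and wind speed.

    The angular axis is the meteorological coming-from direction; the radial
    axis wind speed. Cells observed fewer than ``min_count`` times are
    masked (NaN) — sparse cells say more about sampling than sources.
    """

    species: str
    wd_edges: np.ndarray
    ws_edges: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    min_count: int = 3

    @property
    def n_matched(self) -> int:
        return int(self.counts.sum())


def polar_bin(
    series: VOCTimeSeries,
    met: pd.DataFrame,
    wd_bin_deg: float = 10.0,
    ws_bin_ms: float = 1.0,
    min_count: int = 3,
    tolerance_s: float = 60.0,
) -> PolarGrid:
    """Join VOC and met records by nearest timestamp and grid the means.

    ``met`` needs columns ``time``, ``wd_deg``, ``ws_ms``. Records with no
    met match within ``tolerance_s`` are dropped.
    """
    voc = series.data[["time", "vmr_ppbv"]].sort_values("time")
    m = met[["time", "wd_deg", "ws_ms"]].sort_values("time")
    joined = pd.merge_asof(
        voc, m, on="time", direction="nearest",
        tolerance=pd.Timedelta(seconds=tolerance_s),
    ).dropna(subset=["wd_deg", "ws_ms"])
    if joined.empty:
        raise ValueError(f"{series.species}: no VOC/met timestamp overlap")
    wd_edges = np.arange(0.0, 360.0 + wd_bin_deg / 2, wd_bin_deg)
    ws_max = float(joined["ws_ms"].max())
    ws_edges = np.arange(0.0, ws_max + ws_bin_ms, ws_bin_ms)
    if ws_edges[-1] <= ws_max:
        ws_edges = np.append(ws_edges, ws_edges[-1] + ws_bin_ms)
    wi = np.clip(np.searchsorted(wd_edges, joined["wd_deg"].to_numpy() % 360.0, "right") - 1,
                 0, len(wd_edges) - 2)
    si = np.clip(np.searchsorted(ws_edges, joined["ws_ms"].to_numpy(), "right") - 1,
                 0, len(ws_edges) - 2)
    shape = (len(wd_edges) - 1, len(ws_edges) - 1)
    counts = np.zeros(shape)
    sums = np.zeros(shape)
    np.add.at(counts, (wi, si), 1.0)
    np.add.at(sums, (wi, si), joined["vmr_ppbv"].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= max(min_count, 1), sums / np.maximum(counts, 1), np.nan)
    return PolarGrid(
        species=series.species,
        wd_edges=wd_edges,
        ws_edges=ws_edges,
        means=means,
        counts=counts.astype(int),
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# lifetimes and gradient ranges

@dataclass(frozen=True)
class LifetimeSpec:
    """OH-reactivity lifetime and e-folding transport range of one species."""

    species: str
    k_oh: float                 # cm^3 molecule^-1 s^-1
    oh_conc: float = DEFAULT_OH_CONC
    wind_speed_ms: float = DEFAULT_WIND_SPEED_MS

    @property
    def tau_s(self) -> float:
        return oh_lifetime(self.k_oh, self.oh_conc)

    @property
    def tau_h(self) -> float:
        return self.tau_s / 3600.0

    @property
    def efold_km(self) -> float:
        return efolding_distance(self.tau_s, self.wind_speed_ms)


def oh_lifetime(k_oh: float, oh_conc: float = DEFAULT_OH_CONC) -> float:
    """Pseudo-first-order OH lifetime tau = 1/(k_OH [OH]), seconds."""
    if k_oh <= 0 or oh_conc <= 0:
        raise ValueError("k_oh and oh_conc must be positive")
    return 1.0 / (k_oh * oh_conc)


def efolding_distance(tau_s: float, wind_speed_ms: float = DEFAULT_WIND_SPEED_MS) -> float:
    """Downwind distance (km) over which concentration decays to 1/e."""
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    if wind_speed_ms < 0:
        raise ValueError("wind speed must be non-negative")
    return wind_speed_ms * tau_s / 1000.0


def load_rate_constants() -> pd.DataFrame:
    """Packaged table of recommended k_OH values (species, k_oh, source)."""
    with resources.files("olfnav.data").joinpath("oh_rate_constants.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def lifetime_table(
    oh_conc: float = DEFAULT_OH_CONC,
    wind_speed_ms: float = DEFAULT_WIND_SPEED_MS,
    species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Lifetimes and e-folding ranges for the packaged rate-constant table."""
    k = load_rate_constants()
    if species is not None:
        k = k[k["species"].isin(species)]
    tau = 1.0 / (k["k_oh"].to_numpy(dtype=float) * oh_conc)
    out = k[["species", "k_oh"]].copy()
    out["tau_s"] = tau
    out["tau_h"] = tau / 3600.0
    out["efold_km"] = wind_speed_ms * tau / 1000.0
    return out.reset_index(drop=True)
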