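"""Argos fix-table reading and manual track filtering.

Fix tables are plain pandas DataFrames with columns ``animal_id``, ``time``
(timezone-aware UTC), ``lon``, ``lat``, ``quality``.  The filters mirror the
manual cleaning a telemetry analyst applies after the Argos service's own
Kalman location processing: discard the unusable class-Z fixes and any
position on land, resolve duplicate timestamps, remove fixes implying
biologically impossible speeds (default ceiling 7 m/s for a fin whale), and
truncate a track once the animal definitively leaves the study area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("DeployID", "Date", "Quality", "Latitude", "Longitude")
ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
# higher rank = better quality, used for duplicate resolution
_CLASS_RANK = {c: r for r, c in enumerate(("Z", "B", "A", "0", "1", "2", "3"))}

FIX_COLUMNS = ["animal_id", "time", "lon", "lat", "quality"]


@dataclass
class FilterRules:
    """Manual-filter configuration.

    ``vmax`` is the speed ceiling in m/s; ``truncations`` maps animal id to
    the UTC instant after which fixes are dropped for that animal only.
    """

    drop_classes: frozenset = frozenset({"Z"})
    land_mask: object | None = None  # shapely geometry in lon/lat, or None
    vmax: float = 7.0
    truncations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")


def read_argos_csv(path, dialect: str = "wildlife_computers") -> pd.DataFrame:
    """Read an Argos fix table in the Wildlife Computers CSV dialect.

    Columns DeployID, Date ("HH:MM:SS dd-mmm-yyyy"; ISO 8601 also accepted),
    Quality, Latitude, Longitude.  Rows whose coordinates or timestamps do
    not parse, or whose coordinates are out of range, are reported and
    dropped.  Returns the fix table sorted by (animal, time).
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        warnings.warn(f"{path}: header-only file, no fixes read")
        return pd.DataFrame(columns=FIX_COLUMNS)

    time = pd.to_datetime(raw["Date"], format="%H:%M:%S %d-%b-%Y",
                          errors="coerce", utc=True)
    iso = time.isna()
    if iso.any():  # fall back to ISO 8601 for rows the WC format rejects
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            time[iso] = pd.to_datetime(raw.loc[iso, "Date"], errors="coerce", utc=True)
    lon = pd.to_numeric(raw["Longitude"], errors="coerce")
    lat = pd.to_numeric(raw["Latitude"], errors="coerce")
    qual = raw["Quality"].astype(str).str.strip()

    ok = (time.notna() & lon.notna() & lat.notna()
          & (lon.abs() <= 180.0) & (lat.abs() <= 90.0) & qual.isin(ARGOS_CLASSES))
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} unparseable/out-of-range row(s)")
    fixes = pd.DataFrame({
        "animal_id": raw["DeployID"].astype(str),
        "time": time,
        "lon": lon.astype(float),
        "lat": lat.astype(float),
        "quality": qual,
    })[ok].sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)
    for aid, grp in fixes.groupby("animal_id"):
        log.info("read %d raw locations for %s", len(grp), aid)
    return fixes


def _dedupe(fixes: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate (animal, timestamp) pairs: keep the better class,
    else the first occurrence."""
    rank = fixes["quality"].map(_CLASS_RANK)
    order = fixes.assign(_rank=rank).sort_values(
        ["animal_id", "time", "_rank"], ascending=[True, True, False], kind="stable")
    out = order.drop_duplicates(["animal_id", "time"], keep="first")
    return out.drop(columns="_rank").sort_values(
        ["animal_id", "time"], kind="stable").reset_index(drop=True)


def filter_quality_land(fixes: pd.DataFrame, rules: FilterRules) -> pd.DataFrame:
    """Drop poor-quality classes and terrestrial fixes.

    Returns retained fixes sorted by (animal, time); removal counts are
    logged per filter.  An all-removed result is allowed (with a warning).
    """
    fixes = _dedupe(fixes)
    keep = ~fixes["quality"].isin(rules.drop_classes)
    n_class = int((~keep).sum())
    out = fixes[keep]
    n_land = 0
    if rules.land_mask is not None and len(out):
        from shapely.geometry import Point
        from shapely.prepared import prep

        land = prep(rules.land_mask)
        on_land = np.array([land.contains(Point(lo, la))
                            for lo, la in zip(out["lon"], out["lat"])])
        n_land = int(on_land.sum())
        out = out[~on_land]
    log.info("quality filter removed %d, land filter removed %d of %d fixes",
             n_class, n_land, len(fixes))
    if len(out) == 0 and len(fixes) > 0:
        warnings.warn("all fixes removed by quality/land filtering")
    return out.reset_index(drop=True)


def _speed_filter_one(grp: pd.DataFrame, vmax: float) -> pd.DataFrame:
    """Forward sweep: whenever a segment exceeds vmax, drop its later fix and
    re-check from the previous retained fix.  The first fix is never removed."""
    t = pd.DatetimeIndex(grp["time"]).asi8 / 1e9  # seconds
    lon = grp["lon"].to_numpy()
    lat = grp["lat"].to_numpy()
    keep = [0]
    for j in range(1, len(grp)):
        i = keep[-1]
        dt = t[j] - t[i]
        if dt <= 0:
            continue  # duplicate timestamp survivor; treat as violation
        v = haversine_km(lon[i], lat[i], lon[j], lat[j]) * 1000.0 / dt
        if v <= vmax:
            keep.append(j)
    return grp.iloc[keep]


def speed_filter(fixes: pd.DataFrame, vmax: float = 7.0) -> pd.DataFrame:
    """Remove fixes implying great-circle speeds above ``vmax`` (m/s).

    Deterministic forward sweep per animal; the output contains no
    consecutive pair exceeding the ceiling, and re-applying the filter is a
    no-op.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    if len(fixes) == 0:
        return fixes.copy()
    parts = [_speed_filter_one(grp.sort_values("time", kind="stable"), vmax)
             for _, grp in fixes.groupby("animal_id", sort=True)]
    out = pd.concat(parts).reset_index(drop=True)
    log.info("speed filter (vmax=%.2f m/s) removed %d of %d fixes",
             vmax, len(fixes) - len(out), len(fixes))
    return out


def truncate_track(fixes: pd.DataFrame, animal_id: str, cutoff) -> pd.DataFrame:
    """Drop fixes strictly after ``cutoff`` (UTC) for one animal.

    Other animals are untouched.  A cutoff before the animal's first fix
    empties that track (with a warning).
    """
    cutoff = pd.Timestamp(cutoff)
    if cutoff.tzinfo is None:
        cutoff = cutoff.tz_localize("UTC")
    mine = fixes["animal_id"] == animal_id
    drop = mine & (fixes["time"] > cutoff)
    out = fixes[~drop].reset_index(drop=True)
    if mine.any() and not (mine & ~drop).any():
        warnings.warn(f"truncation cutoff {cutoff} precedes every fix of {animal_id}; "
                      "track is now empty")
    return out


def apply_filters(fixes: pd.DataFrame, rules: FilterRules) -> pd.DataFrame:
    """Full manual-filter chain: quality/land, speed, per-animal truncation."""
    out = filter_quality_land(fixes, rules)
    out = speed_filter(out, rules.vmax)
    for aid, cutoff in rules.truncations.items():
        out = truncate_track(out, aid, cutoff)
    return out


def summarize_deployments(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-animal deployment summary.

    Columns: first_uplink, last_uplink, n_raw_locations, duration_days
    (calendar-day difference between last and first uplink dates).  The
    frame's ``attrs`` carry the across-animal mean and *population* standard
    deviation (divisor n) of the durations.
    """
    if len(fixes) == 0:
        raise ValueError("no fixes to summarise")
    rows = []
    for aid, grp in fixes.groupby("animal_id", sort=True):
        t0 = grp["time"].min()
        t1 = grp["time"].max()
        rows.append({
            "animal_id": aid,
            "first_uplink": t0,
            "last_uplink": t1,
            "n_raw_locations": len(grp),
            "duration_days": (t1.normalize() - t0.normalize()).days,
        })
    table = pd.DataFrame(rows)
    d = table["duration_days"].to_numpy(dtype=float)
    table.attrs["duration_mean_days"] = float(d.mean())
    table.attrs["duration_sd_days"] = float(d.std(ddof=0))
    return table
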