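"""Overlap of realized ranges with conservation-zone polygons.

Spatial protection in the north-western Mediterranean comes in layers with
very different teeth: SPAMIs with active management plans (Pelagos
Sanctuary, Cetacean Migration Corridor), a PSSA carrying voluntary shipping
measures, and an IMMA with no formal protection.  This module quantifies
what fraction of a core (50%) or home (95%) range falls inside each such
polygon.

Areas are measured in a Lambert azimuthal equal-area frame centred on the
range being assessed (authalic sphere, so equal-area to ellipsoidal
accuracy); zone geometries are user-supplied GeoJSON and never bundled,
since official MPA boundaries are versioned artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import transform as shp_transform

from .geo import LocalTM, laea_forward
from .homerange import IsoplethRegion

__all__ = ["ConservationZone", "read_zones_geojson", "write_zones_geojson",
           "region_to_lonlat", "range_zone_overlap", "overlap_report"]


@dataclass
class ConservationZone:
    """Named zone polygon in WGS84 lon/lat with a protection-status tag."""

    name: str
    geometry: object  # shapely (Multi)Polygon
    status: str = "managed"  # or "unprotected-designation"

    def __post_init__(self):
        if not self.geometry.is_valid:
            raise ValueError(f"zone {self.name!r}: invalid geometry")
        if self.geometry.is_empty:
            raise ValueError(f"zone {self.name!r}: empty geometry")


def read_zones_geojson(path) -> list[ConservationZone]:
    """Read zones from a GeoJSON FeatureCollection; features need a ``name``
    property and may carry ``status``."""
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        zones.append(ConservationZone(
            name=props.get("name", f"zone{len(zones)}"),
            geometry=shape(feat["geometry"]),
            status=props.get("status", "managed"),
        ))
    names = [z.name for z in zones]
    if len(set(names)) != len(names):
        raise ValueError("zone names must be unique within a zone set")
    return zones


def write_zones_geojson(zones, path) -> None:
    feats = [{"type": "Feature",
              "properties": {"name": z.name, "status": z.status},
              "geometry": mapping(z.geometry)} for z in zones]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def region_to_lonlat(region: IsoplethRegion, proj: LocalTM):
    """Undo the track projection: isopleth boundary back to lon/lat."""
    def inv(x, y):
        lon, lat = proj.inverse(np.asarray(x), np.asarray(y))
        return lon, lat
    return shp_transform(inv, region.boundary)


def _to_laea(geom, lon0: float, lat0: float):
    def fwd(lon, lat):
        return laea_forward(np.asarray(lon), np.asarray(lat), lon0, lat0)
    return shp_transform(fwd, geom)


def range_zone_overlap(region_lonlat, zone: ConservationZone) -> float:
    """Percent of a range polygon (lon/lat) covered by a zone.

    Both geometries are projected to an equal-area frame centred on the
    range before intersecting; returns 100 * area(range & zone) / area(range).
    """
    if not zone.geometry.is_valid:
        raise ValueError(f"zone {zone.name!r}: invalid geometry")
    if region_lonlat.is_empty or region_lonlat.area == 0:
        raise ValueError("range polygon is empty; overlap undefined")
    c = region_lonlat.centroid
    reg = _to_laea(region_lonlat, c.x, c.y)
    zon = _to_laea(zone.geometry, c.x, c.y)
    return float(100.0 * reg.intersection(zon).area / reg.area)


def overlap_report(regions_by_year_and_level: dict, zones,
                   proj: LocalTM) -> pd.DataFrame:
    """Long-format overlap table: one row per (zone, year, level).

    ``regions_by_year_and_level`` maps ``(year, level)`` to an
    :class:`IsoplethRegion` (projected metres; ``proj`` undoes the
    projection).  Missing levels yield rows with missing percent and a
    warning, so the table shape is stable.  Percentages are rounded to two
    decimals in the ``percent`` column.
    """
    import warnings

    years = sorted({y for (y, _lvl) in regions_by_year_and_level})
    rows = []
    for zone in zones:
        for year in years:
            for level, label in ((0.50, "core"), (0.95, "home")):
                region = regions_by_year_and_level.get((year, level))
                if region is None:
                    warnings.warn(f"no {label} range for {year}; row left missing")
                    pct = np.nan
                else:
                    pct = range_zone_overlap(region_to_lonlat(region, proj), zone)
                rows.append({"zone": zone.name, "status": zone.status,
                             "year": year, "level": label,
                             "percent": round(pct, 2) if np.isfinite(pct) else np.nan})
    return pd.DataFrame(rows)
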