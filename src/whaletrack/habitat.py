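"""Deterministic chlorophyll-front feeding-habitat model.

Fin whales in the north-western Mediterranean feed on krill that aggregates
along productivity fronts — narrow zones of strong horizontal chlorophyll-a
gradient.  The habitat model is deterministic: each day, the gradient
magnitude of the surface chlorophyll field is scored through a linear ramp
to [0, 1], then multiplied by hard exclusions for unfavourable absolute
chlorophyll levels and for shallow water (with an optional reduced
suitability band over the outer shelf).  Time-integrating the daily habitat
gives a percent frequency of favourable occurrence; cells above 30% form
the *main habitat*, against which track positions can be scored by
distance.

Scoring thresholds are configuration, not constants of this module: the
defaults in :func:`example_params` are illustrative placeholders and a
quantile-based calibration helper is provided
(:func:`calibrate_gradient_ramp`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geo import EARTH_RADIUS_KM, haversine_km

__all__ = ["HabitatParams", "example_params", "chl_gradient", "daily_habitat",
           "integrate_habitat", "main_habitat_mask",
           "distance_to_main_habitat", "calibrate_gradient_ramp"]

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


@dataclass
class HabitatParams:
    """Scoring thresholds of the feeding-habitat model.

    chl_min/chl_max        favourable surface chlorophyll range (mg m^-3)
    grad_ramp              (g0, g1) gradient ramp endpoints (mg m^-3 km^-1):
                           habitat 0 below g0, 1 above g1, linear between
    depth_min              minimum water depth (m); shallower cells score 0
    shelf_band             (d_lo, d_hi) depth band of reduced suitability
    shelf_alpha            multiplier in [0, 1] applied inside shelf_band
    main_threshold         frequency (%) above which a cell is main habitat
    smoothing_days         window of the rolling mean on the daily habitat
    """

    chl_min: float
    chl_max: float
    grad_ramp: tuple[float, float]
    depth_min: float = 0.0
    shelf_band: tuple[float, float] | None = None
    shelf_alpha: float = 1.0
    main_threshold: float = 30.0
    smoothing_days: int = 3

    def __post_init__(self):
        if not (0.0 < self.chl_min < self.chl_max):
            raise ValueError("need 0 < chl_min < chl_max")
        g0, g1 = self.grad_ramp
        if not (g0 < g1):
            raise ValueError("gradient ramp needs g0 < g1")
        if not (0.0 <= self.shelf_alpha <= 1.0):
            raise ValueError("shelf_alpha must lie in [0, 1]")
        if not (0.0 < self.main_threshold < 100.0):
            raise ValueError("main_threshold is a percentage in (0, 100)")
        if self.shelf_band is not None and self.shelf_band[0] >= self.shelf_band[1]:
            raise ValueError("shelf_band needs d_lo < d_hi")


def example_params() -> HabitatParams:
    """Illustrative placeholder thresholds for synthetic experiments.

    These are NOT a published calibration; real use requires thresholds
    calibrated on presence data (see :func:`calibrate_gradient_ramp`).
    """
    return HabitatParams(chl_min=0.10, chl_max=1.00,
                         grad_ramp=(0.0005, 0.0040),
                         depth_min=90.0, shelf_band=(90.0, 200.0),
                         shelf_alpha=0.5)


def _spacing_km(da: xr.DataArray, planar_spacing_km: float | None):
    """Per-cell grid spacing (km) in x (east) and y (north)."""
    if planar_spacing_km is not None:
        return (np.full(da.sizes["lat"], planar_spacing_km),
                planar_spacing_km)
    dlat = float(np.mean(np.diff(da["lat"].values)))
    dlon = float(np.mean(np.diff(da["lon"].values)))
    dx = KM_PER_DEG * dlon * np.cos(np.radians(da["lat"].values))
    dy = KM_PER_DEG * dlat
    return dx, dy


def chl_gradient(chl: xr.DataArray, planar_spacing_km: float | None = None) -> xr.DataArray:
    """Horizontal gradient magnitude of a chlorophyll raster (mg m^-3 km^-1).

    Centred finite differences with spacing in km; the east-west spacing
    shrinks with cos(latitude) on a lon/lat grid (pass ``planar_spacing_km``
    to treat the grid as uniformly planar instead).  Edge cells and cells
    with any missing neighbour are missing in the output.  Works on a single
    day (lat, lon) or a stack (time, lat, lon).
    """
    if chl.sizes["lat"] < 3 or chl.sizes["lon"] < 3:
        raise ValueError("grid must be at least 3x3")
    dx, dy = _spacing_km(chl, planar_spacing_km)
    v = chl.values.astype(float)
    single = v.ndim == 2
    if single:
        v = v[None, ...]
    gx = np.full_like(v, np.nan)
    gy = np.full_like(v, np.nan)
    # NaN in any neighbour propagates through the centred difference
    gx[:, :, 1:-1] = (v[:, :, 2:] - v[:, :, :-2]) / (2.0 * np.asarray(dx)[None, :, None])
    gy[:, 1:-1, :] = (v[:, 2:, :] - v[:, :-2, :]) / (2.0 * dy)
    mag = np.hypot(gx, gy)
    if single:
        mag = mag[0]
    out = xr.DataArray(mag, coords=chl.coords, dims=chl.dims, name="grad_chl",
                       attrs={"units": "mg m-3 km-1",
                              "long_name": "horizontal chlorophyll-a gradient"})
    return out


def daily_habitat(chl: xr.DataArray, grad: xr.DataArray, depth: xr.DataArray,
                  params: HabitatParams) -> xr.DataArray:
    """Daily habitat suitability in [0, 1].

    habitat = ramp(grad) * 1[chl_min <= CHL <= chl_max] * depth_factor,
    where the ramp is linear between the two gradient endpoints and the
    depth factor is 0 below ``depth_min``, ``shelf_alpha`` inside
    ``shelf_band`` and 1 otherwise.  Missing CHL or gradient propagates to
    missing habitat.
    """
    for other in (grad, depth):
        if (chl.sizes["lat"] != other.sizes["lat"]
                or chl.sizes["lon"] != other.sizes["lon"]
                or not np.allclose(chl["lat"].values, other["lat"].values)
                or not np.allclose(chl["lon"].values, other["lon"].values)):
            raise ValueError("chl, gradient and depth grids are misaligned")
    g0, g1 = params.grad_ramp
    ramp = ((grad - g0) / (g1 - g0)).clip(0.0, 1.0)
    chl_ok = xr.where(chl.isnull(), np.nan, ((chl >= params.chl_min) & (chl <= params.chl_max)).astype(float))
    d = depth.values
    depth_factor = np.where(d < params.depth_min, 0.0, 1.0)
    if params.shelf_band is not None:
        lo, hi = params.shelf_band
        in_band = (d >= lo) & (d < hi) & (d >= params.depth_min)
        depth_factor = np.where(in_band, params.shelf_alpha, depth_factor)
    hab = ramp * chl_ok * xr.DataArray(depth_factor, coords=depth.coords, dims=depth.dims)
    hab.name = "habitat"
    hab.attrs = {"long_name": "daily feeding habitat suitability", "units": "1"}
    return hab


def integrate_habitat(habitat_days: xr.DataArray, params: HabitatParams,
                      mode: str = "exceedance") -> xr.DataArray:
    """Time-integrate daily habitat to a percent frequency (0-100).

    ``exceedance`` (default): per cell, 100 x (days whose 3-day-smoothed
    habitat exceeds 0.3) / (valid days).  ``mean``: 100 x time-mean of the
    smoothed continuous value.  Cloud-masked days are excluded from the
    denominator; cells with no valid day are missing.
    """
    if "time" not in habitat_days.dims:
        raise ValueError("habitat stack must have a 'time' dimension")
    w = max(1, int(params.smoothing_days))
    smoothed = habitat_days.rolling(time=w, center=True, min_periods=1).mean()
    valid = smoothed.notnull().sum("time")
    if mode == "exceedance":
        freq = 100.0 * (smoothed > 0.3).where(smoothed.notnull()).sum("time") / valid
    elif mode == "mean":
        freq = 100.0 * smoothed.mean("time", skipna=True)
    else:
        raise ValueError(f"unknown integration mode {mode!r}")
    freq = freq.where(valid > 0)
    freq.name = "habitat_freq"
    freq.attrs = {"units": "%", "long_name": "frequency of favourable feeding habitat"}
    return freq


def main_habitat_mask(freq_percent: xr.DataArray, threshold: float = 30.0) -> xr.DataArray:
    """Boolean main-habitat mask: frequency strictly above ``threshold`` %."""
    mask = (freq_percent > threshold) & freq_percent.notnull()
    mask.name = "main_habitat"
    mask.attrs = {"long_name": f"main habitat (frequency > {threshold}%)"}
    return mask


def distance_to_main_habitat(positions: pd.DataFrame, mask: xr.DataArray,
                             within_km: float = 1.0):
    """Great-circle distance (km) of each lon/lat position to the nearest
    main-habitat cell.

    A position lying inside a mask cell scores 0.  Returns
    ``(distances, fraction_within)`` where the fraction counts positions
    closer than ``within_km``.  An empty mask yields infinite distances,
    fraction 0 and a warning.
    """
    import warnings

    lons = positions["lon"].to_numpy(dtype=float)
    lats = positions["lat"].to_numpy(dtype=float)
    m = mask.values.astype(bool)
    if not m.any():
        warnings.warn("main-habitat mask is empty; all distances infinite")
        return np.full(len(lons), np.inf), 0.0
    glat, glon = np.meshgrid(mask["lat"].values, mask["lon"].values, indexing="ij")
    clon = glon[m]
    clat = glat[m]
    half_lon = float(np.mean(np.diff(mask["lon"].values))) / 2.0
    half_lat = float(np.mean(np.diff(mask["lat"].values))) / 2.0
    d = np.empty(len(lons))
    for i, (lo, la) in enumerate(zip(lons, lats)):
        inside = (np.abs(clon - lo) <= half_lon) & (np.abs(clat - la) <= half_lat)
        d[i] = 0.0 if inside.any() else haversine_km(lo, la, clon, clat).min()
    frac = float(np.mean(d < within_km)) if len(d) else 0.0
    return d, frac


def calibrate_gradient_ramp(presence_gradients, quantiles=(0.05, 0.95)):
    """Set the gradient ramp endpoints from presence data.

    Returns ``(g0, g1, cdf)`` where g0/g1 are the requested quantiles of the
    gradient values sampled at presence locations and ``cdf`` is the
    empirical distribution (sorted values, cumulative fractions) for
    inspection — a pragmatic stand-in for fitting a line to the cumulative
    distribution of presence data.
    """
    g = np.asarray(presence_gradients, dtype=float)
    g = g[np.isfinite(g)]
    if len(g) < 30:
        raise ValueError(f"need >= 30 presence gradient values, got {len(g)}")
    if g.max() == g.min():
        raise ValueError("degenerate presence gradients: all values equal")
    q0, q1 = quantiles
    g0, g1 = np.quantile(g, [q0, q1])
    xs = np.sort(g)
    cdf = pd.DataFrame({"gradient": xs,
                        "cum_fraction": np.arange(1, len(xs) + 1) / len(xs)})
    return float(g0), float(g1), cdf
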