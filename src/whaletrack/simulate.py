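"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: switching
correlated-random-walk whale tracks observed through an Argos-style error
model with duty-cycled transmission gaps, daily chlorophyll-a fields holding
a drifting productivity front, a shelf-break bathymetry, and conservation
zone polygons.  The generator mirrors the field campaign it stands in for:
11 LIMPET-tagged fin whales followed for 8-48 days over three late-spring
seasons in the north-western Mediterranean, transmitting only inside two
daily satellite-visibility windows totalling 11-13 h.

The movement model is the generative twin of the behavioural model fitted
downstream: a 2-state Markov chain (area-restricted search vs transit) with
gamma step lengths and von Mises turning angles per state.  Simulation is
planar in a local transverse-Mercator frame around the origin and exported
as WGS84 lon/lat, since the pipeline re-projects anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Polygon

from .geo import EARTH_RADIUS_KM, LocalTM

__all__ = [
    "SimTrackParams",
    "ArgosErrorModel",
    "FrontFieldSpec",
    "GridSpec",
    "simulate_switching_track",
    "observe_argos",
    "simulate_chl_series",
    "simulate_bathymetry",
    "make_zone",
    "default_fleet_params",
    "DEFAULT_CLASS_SD",
    "DEFAULT_CLASS_FREQ",
]

# Isotropic 1-sigma position error (m) per Argos location class; class Z is
# unusable and assigned a huge sd so that keeping it is visibly wrong.
DEFAULT_CLASS_SD = {"3": 250.0, "2": 500.0, "1": 1500.0, "0": 5000.0,
                    "A": 5000.0, "B": 10000.0, "Z": 50000.0}
# Class mix of a dorsal-fin LIMPET tag on a large whale: short surfacings
# yield mostly low-quality fixes.
DEFAULT_CLASS_FREQ = {"3": 0.04, "2": 0.07, "1": 0.11, "0": 0.14,
                      "A": 0.24, "B": 0.38, "Z": 0.02}


@dataclass
class SimTrackParams:
    """Two-state switching CRW parameters (state 0 = ARS, state 1 = transit).

    Step lengths are gamma with the given per-state mean/sd (km per step);
    turning angles are von Mises with per-state location (rad) and
    concentration kappa.  ``transition`` is the row-stochastic 2x2 matrix of
    the hidden Markov chain at resolution ``dt`` hours.
    """

    n_steps: int = 200
    dt: float = 3.0
    state_means: tuple[float, float] = (2.0, 12.0)
    state_sds: tuple[float, float] = (1.6, 6.0)
    kappas: tuple[float, float] = (0.6, 9.0)
    angle_means: tuple[float, float] = (0.0, 0.0)
    # stay-probabilities give stationary ARS occupancy 0.35/(0.35+0.05)=0.875
    transition: np.ndarray = field(
        default_factory=lambda: np.array([[0.95, 0.05], [0.35, 0.65]]))
    initial: np.ndarray = field(default_factory=lambda: np.array([0.875, 0.125]))
    origin: tuple[float, float] = (4.5, 41.0)  # lon, lat
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2021-05-08 00:00:00", tz="UTC"))
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition must be a 2x2 row-stochastic matrix")
        p0 = np.asarray(self.initial, dtype=float)
        if p0.shape != (2,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-12:
            raise ValueError("initial must be a length-2 probability vector")
        if np.any(np.asarray(self.state_means) <= 0) or np.any(np.asarray(self.state_sds) <= 0):
            raise ValueError("state step means and sds must be positive")
        if np.any(np.asarray(self.kappas) < 0):
            raise ValueError("kappas must be non-negative")
        if self.n_steps < 1 or self.dt <= 0:
            raise ValueError("n_steps >= 1 and dt > 0 required")


@dataclass
class ArgosErrorModel:
    """Observation model of the satellite tag.

    ``duty_windows`` are the daily UTC hour intervals in which the tag may
    transmit (no fix can exist outside them); ``p_fix`` thins path samples
    inside a window to a realistic uplink rate.
    """

    class_sd: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SD))
    class_freq: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQ))
    duty_windows: tuple = ((6.0, 11.0), (16.0, 22.0))
    p_fix: float = 0.9

    def validate(self) -> None:
        if any(sd < 0 for sd in self.class_sd.values()):
            raise ValueError("class sds must be >= 0")
        wins = sorted((float(a), float(b)) for a, b in self.duty_windows)
        for a, b in wins:
            if not (0.0 <= a < b <= 24.0):
                raise ValueError(f"duty window [{a},{b}) must lie within [0,24)")
        for (_, b1), (a2, _) in zip(wins, wins[1:]):
            if a2 < b1:
                raise ValueError("duty windows must not overlap")
        f = np.array(list(self.class_freq.values()), dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("class frequencies must form a probability vector")

    def in_duty(self, times: pd.DatetimeIndex) -> np.ndarray:
        hod = times.hour.values + times.minute.values / 60.0 + times.second.values / 3600.0
        mask = np.zeros(len(times), dtype=bool)
        for a, b in self.duty_windows:
            mask |= (hod >= a) & (hod < b)
        return mask


@dataclass
class GridSpec:
    """Regular lon/lat grid; cell size defaults to 2.5 arc-min (1/24 deg)."""

    lon_min: float = 2.0
    lon_max: float = 8.0
    lat_min: float = 39.5
    lat_max: float = 43.5
    cell_deg: float = 1.0 / 24.0

    def lons(self) -> np.ndarray:
        return np.arange(self.lon_min + self.cell_deg / 2, self.lon_max, self.cell_deg)

    def lats(self) -> np.ndarray:
        return np.arange(self.lat_min + self.cell_deg / 2, self.lat_max, self.cell_deg)


@dataclass
class FrontFieldSpec:
    """Daily chlorophyll fields with a single linear productivity front.

    The field transitions logistically from ``chl_low`` to ``chl_high``
    across a line through ``front_point`` with bearing ``front_bearing_deg``
    (degrees clockwise from north); ``front_width_km`` is the 10%-90%
    transition width.  The front drifts ``drift_km_per_day`` along its
    left normal each day.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    chl_low: float = 0.1
    chl_high: float = 1.5
    front_point: tuple[float, float] = (4.5, 41.2)  # lon, lat
    front_bearing_deg: float = 60.0
    front_width_km: float = 15.0
    drift_km_per_day: float = 2.0
    noise_sd: float = 0.02
    cloud_fraction: float = 0.0
    n_days: int = 30
    start_date: str = "2021-05-08"
    seed: int = 0

    def validate(self) -> None:
        if not (self.chl_high > self.chl_low > 0):
            raise ValueError("need chl_high > chl_low > 0")
        if self.grid.cell_deg <= 0:
            raise ValueError("cell size must be positive")
        if self.front_width_km <= 0 or self.n_days < 1:
            raise ValueError("front_width_km > 0 and n_days >= 1 required")


def simulate_switching_track(params: SimTrackParams):
    """Simulate one switching-CRW track.

    Returns ``(path, states)`` where ``path`` is a DataFrame with columns
    ``time, x, y, lon, lat`` (x/y metres in the local TM frame) holding
    ``n_steps + 1`` positions, and ``states`` is the length-``n_steps``
    Markov-chain realisation (0 = ARS, 1 = transit) driving each step.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_steps

    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=np.asarray(params.initial, dtype=float))
    t = np.asarray(params.transition, dtype=float)
    for i in range(1, n):
        states[i] = rng.choice(2, p=t[states[i - 1]])

    means = np.asarray(params.state_means)[states]
    sds = np.asarray(params.state_sds)[states]
    shape = (means / sds) ** 2
    scale = sds**2 / means
    steps_km = rng.gamma(shape, scale)

    turns = np.empty(n)
    for s in (0, 1):
        m = states == s
        k = params.kappas[s]
        if k == 0:
            turns[m] = rng.uniform(-np.pi, np.pi, m.sum())
        else:
            turns[m] = rng.vonmises(params.angle_means[s], k, m.sum())
    # first turning angle acts on a random initial heading
    headings = rng.uniform(-np.pi, np.pi) + np.cumsum(turns)

    x = np.concatenate([[0.0], np.cumsum(steps_km * 1000.0 * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(steps_km * 1000.0 * np.sin(headings))])

    proj = LocalTM(*params.origin)
    lon, lat = proj.inverse(x, y)
    times = params.start_time + pd.to_timedelta(np.arange(n + 1) * params.dt, unit="h")
    path = pd.DataFrame({"time": times, "x": x, "y": y, "lon": lon, "lat": lat})
    return path, states


def observe_argos(path: pd.DataFrame, model: ArgosErrorModel, seed: int = 0,
                  animal_id: str = "sim001") -> pd.DataFrame:
    """Observe a true path through the Argos error model.

    Path samples falling inside a duty window are retained with probability
    ``p_fix``, perturbed by class-dependent isotropic Gaussian noise, and
    assigned an i.i.d. location class from the class-frequency table.
    Returns a table in the Wildlife Computers CSV dialect
    (DeployID, Date, Quality, Latitude, Longitude) sorted by time.
    """
    model.validate()
    if len(path) == 0:
        return pd.DataFrame(columns=["DeployID", "Date", "Quality", "Latitude", "Longitude"])
    times = pd.DatetimeIndex(path["time"])
    if not times.is_monotonic_increasing or times.duplicated().any():
        raise ValueError("path timestamps must be strictly increasing")
    rng = np.random.default_rng(seed)

    keep = model.in_duty(times) & (rng.random(len(times)) < model.p_fix)
    sub = path.loc[keep].reset_index(drop=True)
    classes = np.array(list(model.class_freq.keys()))
    probs = np.array(list(model.class_freq.values()), dtype=float)
    qual = rng.choice(classes, size=len(sub), p=probs / probs.sum())
    sd = np.array([model.class_sd[q] for q in qual])

    proj = LocalTM(float(sub["lon"].iloc[0]) if len(sub) else 0.0,
                   float(sub["lat"].iloc[0]) if len(sub) else 0.0)
    if len(sub):
        x, y = proj.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        x = x + rng.normal(0.0, 1.0, len(sub)) * sd
        y = y + rng.normal(0.0, 1.0, len(sub)) * sd
        lon, lat = proj.inverse(x, y)
    else:
        lon = lat = np.array([])
    date = pd.DatetimeIndex(sub["time"]).strftime("%H:%M:%S %d-%b-%Y")
    return pd.DataFrame({
        "DeployID": animal_id,
        "Date": date,
        "Quality": qual,
        "Latitude": lat,
        "Longitude": lon,
    })


def _cross_track_km(spec: FrontFieldSpec, lon2d, lat2d, day: int):
    """Signed distance (km) from each cell to the (drifted) front line, on a
    local planar approximation around the front point."""
    lon0, lat0 = spec.front_point
    xk = (lon2d - lon0) * np.cos(np.radians(lat0)) * np.pi / 180.0 * EARTH_RADIUS_KM
    yk = (lat2d - lat0) * np.pi / 180.0 * EARTH_RADIUS_KM
    b = np.radians(spec.front_bearing_deg)
    # unit vector along the front (bearing from north) and its left normal
    ux, uy = np.sin(b), np.cos(b)
    nx, ny = -uy, ux
    return xk * nx + yk * ny - day * spec.drift_km_per_day


def simulate_chl_series(spec: FrontFieldSpec) -> xr.DataArray:
    """Daily chlorophyll rasters (mg m^-3) with a drifting logistic front.

    Returns a DataArray ``chl(time, lat, lon)``; cloud gaps (if requested)
    are i.i.d. per-cell NaN masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lons = spec.grid.lons()
    lats = spec.grid.lats()
    lon2d, lat2d = np.meshgrid(lons, lats)
    # logistic 10-90% width w  =>  scale s = w / (2 ln 9)
    s = spec.front_width_km / (2.0 * np.log(9.0))
    days = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    fields = np.empty((spec.n_days, len(lats), len(lons)))
    for d in range(spec.n_days):
        dist = _cross_track_km(spec, lon2d, lat2d, d)
        f = spec.chl_low + (spec.chl_high - spec.chl_low) / (1.0 + np.exp(-dist / s))
        if spec.noise_sd > 0:
            f = f + rng.normal(0.0, spec.noise_sd, f.shape)
        if spec.cloud_fraction > 0:
            f = np.where(rng.random(f.shape) < spec.cloud_fraction, np.nan, f)
        fields[d] = f
    return xr.DataArray(
        fields,
        coords={"time": days, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="chl",
        attrs={"units": "mg m-3", "long_name": "surface chlorophyll-a"},
    )


def simulate_bathymetry(grid: GridSpec, shelf_spec: dict | None = None) -> xr.DataArray:
    """Static depth raster (m, positive down).

    ``shelf_spec`` kinds: ``constant`` (``depth``) or ``linear`` — depth
    increasing from ``coast_depth`` at latitude ``coast_lat`` southwards at
    ``slope_m_per_km`` down to ``max_depth``.
    """
    shelf_spec = shelf_spec or {"kind": "linear", "coast_lat": 43.3,
                                "coast_depth": 0.0, "slope_m_per_km": 25.0,
                                "max_depth": 2500.0}
    lons = grid.lons()
    lats = grid.lats()
    lon2d, lat2d = np.meshgrid(lons, lats)
    if shelf_spec["kind"] == "constant":
        depth = np.full(lon2d.shape, float(shelf_spec["depth"]))
    elif shelf_spec["kind"] == "linear":
        dist_km = (shelf_spec["coast_lat"] - lat2d) * np.pi / 180.0 * EARTH_RADIUS_KM
        depth = shelf_spec["coast_depth"] + shelf_spec["slope_m_per_km"] * np.clip(dist_km, 0.0, None)
        depth = np.minimum(depth, shelf_spec["max_depth"])
    else:
        raise ValueError(f"unknown shelf kind {shelf_spec['kind']!r}")
    return xr.DataArray(depth, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"), name="depth",
                        attrs={"units": "m", "positive": "down"})


def make_zone(polygon_spec: dict):
    """Build a conservation zone from a spec dict.

    ``polygon_spec`` needs ``name``, ``coords`` (list of (lon, lat)) and an
    optional ``status`` (``managed`` or ``unprotected-designation``).
    Self-intersecting rings are rejected.
    """
    from .conservation import ConservationZone

    poly = Polygon(polygon_spec["coords"])
    if not poly.is_valid:
        raise ValueError(f"zone {polygon_spec.get('name')!r}: polygon is invalid "
                         "(self-intersecting or degenerate)")
    return ConservationZone(
        name=polygon_spec["name"],
        geometry=poly,
        status=polygon_spec.get("status", "managed"),
    )


def default_fleet_params(seed: int = 0) -> list[SimTrackParams]:
    """Study-condition fleet: 11 whales across three seasons, 8-48 days.

    Durations and deployment dates echo the real campaign (three whales in
    May 2021, five in May 2022, three in June 2023); at the 3-h resolution a
    d-day track has 8*d steps.
    """
    seasons = [
        ("2021-05-08", 14), ("2021-05-06", 31), ("2021-05-07", 24),
        ("2022-05-12", 9), ("2022-05-12", 26), ("2022-05-14", 25),
        ("2022-05-15", 23), ("2022-05-15", 8),
        ("2023-06-04", 48), ("2023-06-05", 16), ("2023-06-05", 35),
    ]
    rng = np.random.default_rng(seed)
    fleet = []
    for i, (date, days) in enumerate(seasons):
        lon0 = 3.0 + rng.uniform(0.0, 2.5)
        lat0 = 40.5 + rng.uniform(0.0, 1.5)
        fleet.append(SimTrackParams(
            n_steps=8 * days,
            start_time=pd.Timestamp(date + " 06:00:00", tz="UTC"),
            origin=(lon0, lat0),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return fleet
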