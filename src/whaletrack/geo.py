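"""Geodesy helpers: projections, distances and polygon areas.

All public functions operate on WGS84 longitude/latitude in degrees and on
planar coordinates in metres.  Three pieces are provided:

* an ellipsoidal transverse Mercator (Krueger series), used to place tracks
  on a local planar frame for step/turn metrics and kernel density work;
* an equal-area projection (Lambert azimuthal on the authalic sphere), used
  whenever an *area ratio* has to be trusted to better than 0.1%;
* a geodesic polygon area on the authalic sphere, used as the independent
  check on projected areas.

The transverse Mercator series is the standard fourth-order expansion in the
third flattening and is accurate to well under a millimetre over the few
hundred kilometres the tracks span.
"""

from __future__ import annotations

import math

import numpy as np

# WGS84
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)
EARTH_RADIUS_KM = 6371.0088  # mean radius, haversine work

_N3 = WGS84_F / (2.0 - WGS84_F)  # third flattening n
# Rectifying radius A = a/(1+n) (1 + n^2/4 + n^4/64 + ...)
_RECT_A = WGS84_A / (1.0 + _N3) * (1.0 + _N3**2 / 4.0 + _N3**4 / 64.0)
# Krueger alpha (forward) and beta (inverse) coefficients, O(n^4)
_ALPHA = (
    _N3 / 2.0 - 2.0 * _N3**2 / 3.0 + 5.0 * _N3**3 / 16.0 + 41.0 * _N3**4 / 180.0,
    13.0 * _N3**2 / 48.0 - 3.0 * _N3**3 / 5.0 + 557.0 * _N3**4 / 1440.0,
    61.0 * _N3**3 / 240.0 - 103.0 * _N3**4 / 140.0,
    49561.0 * _N3**4 / 161280.0,
)
_BETA = (
    _N3 / 2.0 - 2.0 * _N3**2 / 3.0 + 37.0 * _N3**3 / 96.0 - _N3**4 / 360.0,
    _N3**2 / 48.0 + _N3**3 / 15.0 - 437.0 * _N3**4 / 1440.0,
    17.0 * _N3**3 / 480.0 - 37.0 * _N3**4 / 840.0,
    4397.0 * _N3**4 / 161280.0,
)


def utm_zone_from_lon(lon: float) -> int:
    """UTM zone number (1-60) containing longitude ``lon``."""
    return int((float(lon) + 180.0) // 6.0) % 60 + 1


def utm_central_lon(zone: int) -> float:
    return -183.0 + 6.0 * int(zone)


def tm_forward(lon, lat, lon0: float, k0: float = 0.9996):
    """Ellipsoidal transverse Mercator, central meridian ``lon0``.

    Returns easting/northing in metres (no false offsets; northing is
    measured from the equator).  Vectorised over ``lon``/``lat``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon - lon0)

    # conformal latitude
    e = math.sqrt(WGS84_E2)
    s = np.sin(phi)
    t = np.sinh(np.arctanh(s) - e * np.arctanh(e * s))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
    return k0 * _RECT_A * eta, k0 * _RECT_A * xi


def tm_inverse(x, y, lon0: float, k0: float = 0.9996):
    """Inverse of :func:`tm_forward`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xi = y / (k0 * _RECT_A)
    eta = x / (k0 * _RECT_A)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))  # conformal latitude
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # invert conformal -> geodetic latitude by fixed point (converges fast)
    e = math.sqrt(WGS84_E2)
    phi = chi.copy()
    for _ in range(8):
        s = np.sin(phi)
        phi = np.arcsin(np.tanh(np.arctanh(np.sin(chi)) + e * np.arctanh(e * s)))
    return np.degrees(lam) + lon0, np.degrees(phi)


class LocalTM:
    """Transverse Mercator frame anchored at an origin point.

    Coordinates are metres east/north of ``(lon0, lat0)``; the central
    meridian passes through the origin so scale distortion stays negligible
    for a regional tracking dataset.
    """

    def __init__(self, lon0: float, lat0: float = 0.0, k0: float = 1.0):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.k0 = float(k0)
        _, self._y0 = tm_forward(lon0, lat0, lon0, k0)

    def forward(self, lon, lat):
        x, y = tm_forward(lon, lat, self.lon0, self.k0)
        return x, y - self._y0

    def inverse(self, x, y):
        return tm_inverse(x, np.asarray(y, dtype=float) + self._y0, self.lon0, self.k0)

    @property
    def tag(self) -> str:
        return f"tmerc:lon0={self.lon0:.6f},lat0={self.lat0:.6f},k0={self.k0}"


# ---------------------------------------------------------------------------
# equal-area machinery (authalic sphere)

def _authalic_q(phi: np.ndarray) -> np.ndarray:
    e = math.sqrt(WGS84_E2)
    s = np.sin(phi)
    return (1.0 - WGS84_E2) * (
        s / (1.0 - WGS84_E2 * s**2) - (1.0 / (2.0 * e)) * np.log((1.0 - e * s) / (1.0 + e * s))
    )


_QP = float(_authalic_q(np.array(math.pi / 2.0)))
AUTHALIC_RADIUS = WGS84_A * math.sqrt(_QP / 2.0)  # ~6371007.18 m


def authalic_lat(lat) -> np.ndarray:
    """Authalic latitude (radians) of geodetic latitude ``lat`` (degrees)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    return np.arcsin(np.clip(_authalic_q(phi) / _QP, -1.0, 1.0))


def laea_forward(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area on the authalic sphere (metres).

    Equal-area to ellipsoidal accuracy because geodetic latitudes are first
    mapped to authalic latitudes.
    """
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    beta = authalic_lat(lat)
    beta0 = float(authalic_lat(lat0))
    denom = 1.0 + math.sin(beta0) * np.sin(beta) + math.cos(beta0) * np.cos(beta) * np.cos(lam)
    k = np.sqrt(2.0 / denom)
    x = AUTHALIC_RADIUS * k * np.cos(beta) * np.sin(lam)
    y = AUTHALIC_RADIUS * k * (
        math.cos(beta0) * np.sin(beta) - math.sin(beta0) * np.cos(beta) * np.cos(lam)
    )
    return x, y


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (degrees); vectorised."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def geodesic_polygon_area_km2(lons, lats) -> float:
    """Area (km^2) of a lon/lat polygon ring, via the line integral on the
    authalic sphere.  Independent of the projection-based route, so it serves
    as an oracle for projected areas; exact for edges that are short relative
    to the Earth's radius.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons[0] != lons[-1] or lats[0] != lats[-1]:
        lons = np.append(lons, lons[0])
        lats = np.append(lats, lats[0])
    lam = np.radians(lons)
    beta = authalic_lat(lats)
    # trapezoid rule on the equal-area cylinder: dA = R^2 * sin(beta) dlam
    s = np.sum((lam[1:] - lam[:-1]) * (np.sin(beta[1:]) + np.sin(beta[:-1])) / 2.0)
    return abs(s) * (AUTHALIC_RADIUS / 1000.0) ** 2
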