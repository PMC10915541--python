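"""Kernel utilization distributions, isopleth ranges and overlap indices.

A utilization distribution (UD) is the probability surface of an animal's
space use, estimated here by a bivariate normal kernel density over the
regularized positions, gridded at 10x10 km by default.  Because positions
are temporally equidistant, the mass inside a region reads directly as the
fraction of tracked time spent there: the 50% isopleth is the core range,
the 95% isopleth the home range.

Two overlap indices are provided: the asymmetric percent-overlap of
isopleth areas, and the Bhattacharyya affinity computed on UDs truncated to
their own isopleths *without renormalisation*, which caps the index at 0.95
for home ranges and 0.50 for core ranges (self-affinity then equals the
contained isopleth mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

__all__ = ["UDGrid", "IsoplethRegion", "href_bandwidth", "make_grid",
           "kernel_ud", "isopleth", "percent_overlap", "bhattacharyya",
           "pooled_ud"]


@dataclass
class UDGrid:
    """Gridded probability mass (rows = y, cols = x), cells sum to 1."""

    x0: float            # west edge of cell (0,0), metres
    y0: float            # south edge, metres
    cell_size: float     # metres
    mass: np.ndarray     # (ny, nx)
    projection: str = ""
    h: float = float("nan")  # bandwidth used (m)

    @property
    def nx(self) -> int:
        return self.mass.shape[1]

    @property
    def ny(self) -> int:
        return self.mass.shape[0]

    def cell_centers(self):
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return cx, cy

    def same_grid(self, other: "UDGrid") -> bool:
        return (self.mass.shape == other.mass.shape
                and abs(self.x0 - other.x0) < 1e-6
                and abs(self.y0 - other.y0) < 1e-6
                and abs(self.cell_size - other.cell_size) < 1e-9)


@dataclass
class IsoplethRegion:
    """Minimal highest-density cell set holding >= ``level`` of the UD mass."""

    level: float
    cell_indices: np.ndarray      # flat row-major indices into the UD grid
    contained_mass: float
    boundary: object              # shapely (Multi)Polygon, projected metres
    area_km2: float
    projection: str = ""


def href_bandwidth(points: np.ndarray) -> float:
    """Reference (*ad hoc*) bandwidth h = 0.5 (sd_x + sd_y) n^(-1/6).

    ``points`` is (n, 2) in metres; coordinate sds use divisor n-1.  This is
    the convention of the classic home-range software for a bivariate
    normal kernel.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n>=2, 2) point array")
    sd = pts.std(axis=0, ddof=1)
    if np.any(sd == 0) and sd.sum() == 0:
        raise ValueError("degenerate point cloud: zero spread in both coordinates")
    return float(0.5 * sd.sum() * len(pts) ** (-1.0 / 6.0))


def make_grid(points: np.ndarray, cell_size: float = 10_000.0,
              h: float | None = None, margin_factor: float = 3.0,
              projection: str = "") -> UDGrid:
    """Empty grid covering ``points`` padded by ``margin_factor * h`` and
    snapped to whole cells."""
    pts = np.asarray(points, dtype=float)
    h = href_bandwidth(pts) if h is None else float(h)
    pad = margin_factor * h
    x0 = np.floor((pts[:, 0].min() - pad) / cell_size) * cell_size
    y0 = np.floor((pts[:, 1].min() - pad) / cell_size) * cell_size
    nx = int(np.ceil((pts[:, 0].max() + pad - x0) / cell_size))
    ny = int(np.ceil((pts[:, 1].max() + pad - y0) / cell_size))
    return UDGrid(x0=x0, y0=y0, cell_size=cell_size,
                  mass=np.zeros((ny, nx)), projection=projection, h=h)


def kernel_ud(points: np.ndarray, grid: UDGrid | None = None,
              h: float | None = None, cell_size: float = 10_000.0,
              projection: str = "") -> UDGrid:
    """Bivariate-normal kernel UD of ``points`` (metres) on a grid.

    The density is the average of isotropic Gaussian kernels (sd ``h``,
    default the reference bandwidth) evaluated at cell centres, multiplied
    by the cell area and renormalised so the masses sum to exactly 1.
    """
    pts = np.asarray(points, dtype=float)
    h = href_bandwidth(pts) if h is None else float(h)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = make_grid(pts, cell_size=cell_size, h=h, projection=projection)
    cx, cy = grid.cell_centers()
    margin = 3.0 * h
    if (pts[:, 0].min() - grid.x0 < margin
            or grid.x0 + grid.nx * grid.cell_size - pts[:, 0].max() < margin
            or pts[:, 1].min() - grid.y0 < margin
            or grid.y0 + grid.ny * grid.cell_size - pts[:, 1].max() < margin):
        raise ValueError("grid does not cover the points with a 3h margin; "
                         "enlarge it (make_grid pads by 3h automatically)")
    # separable Gaussian: sum_p N(cx|x_p) outer N(cy|y_p)
    gx = np.exp(-0.5 * ((cx[None, :] - pts[:, 0][:, None]) / h) ** 2)
    gy = np.exp(-0.5 * ((cy[None, :] - pts[:, 1][:, None]) / h) ** 2)
    dens = (gy[:, :, None] * gx[:, None, :]).sum(axis=0) / (len(pts) * 2.0 * np.pi * h**2)
    mass = dens * grid.cell_size**2
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total mass on the grid")
    return UDGrid(x0=grid.x0, y0=grid.y0, cell_size=grid.cell_size,
                  mass=mass / total, projection=projection or grid.projection, h=h)


def isopleth(ud: UDGrid, level: float) -> IsoplethRegion:
    """Highest-density region containing at least ``level`` of the mass.

    Cells are ranked by density descending (ties broken by row-major index)
    and the smallest prefix reaching the level is kept; the boundary is the
    union of the member cell squares and the area is the member count times
    the cell area.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")  # stable: row-major among ties
    csum = np.cumsum(flat[order])
    if level >= csum[-1]:
        k = int(np.sum(flat > 0))
    else:
        k = int(np.searchsorted(csum, level) + 1)
    members = order[:k]
    members = members[flat[members] > 0]
    contained = float(flat[members].sum())

    cs = ud.cell_size
    boxes = []
    for idx in members:
        r, c = divmod(int(idx), ud.nx)
        x = ud.x0 + c * cs
        y = ud.y0 + r * cs
        boxes.append(box(x, y, x + cs, y + cs))
    boundary = unary_union(boxes) if boxes else box(0, 0, 0, 0)
    return IsoplethRegion(level=float(level), cell_indices=np.sort(members),
                          contained_mass=contained, boundary=boundary,
                          area_km2=len(members) * (cs / 1000.0) ** 2,
                          projection=ud.projection)


def percent_overlap(region_i: IsoplethRegion, region_j: IsoplethRegion) -> float:
    """Fraction of region i's area overlapped by region j (asymmetric)."""
    if abs(region_i.level - region_j.level) > 1e-12:
        raise ValueError("regions must share the isopleth level")
    if region_i.projection != region_j.projection:
        raise ValueError("regions must share a projection")
    a_i = region_i.boundary.area
    if a_i <= 0:
        raise ValueError("region i has zero area; percent overlap undefined")
    return float(region_i.boundary.intersection(region_j.boundary).area / a_i)


def bhattacharyya(ud_i: UDGrid, ud_j: UDGrid, level: float = 0.95) -> float:
    """Truncated Bhattacharyya affinity BA = sum_cells sqrt(p_i p_j).

    Each UD is first truncated to its *own* level-isopleth cells (mass
    outside set to zero, not renormalised), so the ceiling of the index is
    the level itself: 0.95 for home ranges, 0.50 for core ranges.
    """
    if not ud_i.same_grid(ud_j):
        raise ValueError("UDs must live on an identical grid")
    p = np.zeros(ud_i.mass.size)
    q = np.zeros(ud_j.mass.size)
    ri = isopleth(ud_i, level)
    rj = isopleth(ud_j, level)
    p[ri.cell_indices] = ud_i.mass.ravel()[ri.cell_indices]
    q[rj.cell_indices] = ud_j.mass.ravel()[rj.cell_indices]
    return float(np.sqrt(p * q).sum())


def pooled_ud(tracks: pd.DataFrame, grouping: str | None = None,
              cell_size: float = 10_000.0, grid: UDGrid | None = None,
              projection: str = "") -> dict:
    """Pooled-position UDs per group (e.g. per year).

    Every regular position carries equal weight, so pooling animals within
    a group weights each by its tracking duration; the reference bandwidth
    is computed on the pooled point set.  Returns ``{group: UDGrid}``; with
    ``grouping=None`` a single group ``"all"``.
    """
    if grouping is None:
        groups = {"all": tracks}
    else:
        groups = {g: grp for g, grp in tracks.groupby(grouping, sort=True)}
    out = {}
    for g, grp in groups.items():
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        out[g] = kernel_ud(pts, grid=grid, cell_size=cell_size,
                           projection=projection or tracks.attrs.get("projection", ""))
    return out
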