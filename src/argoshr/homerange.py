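"""Home-range estimators: 95% minimum convex polygon and 95% fixed kernel.

Both operate on planar point sets (metres). The MCP retains the fraction of
points nearest the arithmetic centroid and takes their convex hull. The
kernel estimator evaluates a bivariate-normal kernel utilization
distribution (UD) on a regular grid and returns the smallest set of cells
holding the requested UD mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .geo import PlanarPoint


def as_xy(points) -> np.ndarray:
    """Coerce a point collection ((n,2) array or sequence of PlanarPoint) to
    an (n, 2) float array."""
    if isinstance(points, np.ndarray):
        pts = np.asarray(points, dtype=float)
    else:
        points = list(points)
        if points and isinstance(points[0], PlanarPoint):
            crs = {p.crs for p in points}
            if len(crs) > 1:
                raise ValueError("points span multiple planar frames")
            pts = np.array([(p.x, p.y) for p in points], dtype=float)
        else:
            pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class KDEConfig:
    """Kernel UD settings: bandwidth ``h`` and grid cell size in metres.

    ``margin`` is how far the grid extends beyond the point bounding box
    (default 4h, where the kernel mass is negligible); ``level`` is the UD
    isopleth defining the home range.
    """

    h: float = 850.0
    cell: float = 250.0
    margin: float | None = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.h <= 0 or self.cell <= 0:
            raise ValueError("h and cell must be positive")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @property
    def margin_m(self) -> float:
        return 4.0 * self.h if self.margin is None else self.margin


@dataclass
class GriddedUD:
    """A kernel utilization distribution on a regular grid.

    ``mass[i, j]`` is the probability mass of the cell whose center is
    ``(x0 + (j + 0.5) cell, y0 + (i + 0.5) cell)``; masses sum to 1.
    """

    x0: float
    y0: float
    cell: float
    mass: np.ndarray


@dataclass
class HomeRange:
    """A home-range estimate: its method, area (m²) and geometry.

    For ``mcp95`` the geometry is the hull vertex array (counter-clockwise);
    for ``kde95`` it is the occupied cell index set on the UD grid.
    """

    method: str
    area: float
    vertices: np.ndarray | None = None
    grid: GriddedUD | None = None
    cells: np.ndarray | None = None  # (m, 2) array of (i, j) occupied cells

    @property
    def area_km2(self) -> float:
        return self.area / 1e6

    def polygon(self) -> Polygon:
        if self.vertices is None:
            raise ValueError("only MCP home ranges have a polygon")
        return Polygon(self.vertices)


def mcp95(points, level: float = 0.95) -> HomeRange:
    """Minimum convex polygon of the points nearest the arithmetic centroid.

    Points whose centroid distance is at most the ``level`` quantile
    (linear-interpolation rule) of all centroid distances are retained —
    the convention of the standard home-range software, which at ``level``
    0.95 discards slightly more than 5% of locations for small samples. At
    least 5 non-collinear points are required.
    """
    pts = as_xy(points)
    n = len(pts)
    if n < 5:
        raise ValueError(f"MCP needs at least 5 points, got {n}")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    sel = pts[d <= np.quantile(d, level, method="linear")]
    try:
        hull = ConvexHull(sel)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear) point set: {e}") from None
    if hull.volume <= 0:
        raise ValueError("degenerate hull with zero area")
    return HomeRange(method="mcp95", area=float(hull.volume), vertices=sel[hull.vertices])


def kde_ud(points, cfg: KDEConfig = KDEConfig()) -> GriddedUD:
    """Bivariate-normal kernel UD on a regular grid.

    The grid covers the point bounding box expanded by ``cfg.margin_m``, with
    its origin snapped to multiples of the cell size so repeated runs over
    the same frame share cell boundaries. Cell masses (density at the cell
    center times cell area) are renormalized to sum to exactly 1, making the
    isopleth prefix well defined on the finite grid.
    """
    pts = as_xy(points)
    if len(pts) == 0:
        raise ValueError("kernel UD of an empty point set")
    c, h, m = cfg.cell, cfg.h, cfg.margin_m
    x0 = np.floor((pts[:, 0].min() - m) / c) * c
    y0 = np.floor((pts[:, 1].min() - m) / c) * c
    nx = int(np.ceil((pts[:, 0].max() + m - x0) / c))
    ny = int(np.ceil((pts[:, 1].max() + m - y0) / c))
    xc = x0 + (np.arange(nx) + 0.5) * c
    yc = y0 + (np.arange(ny) + 0.5) * c
    # squared distances cell-center -> point, separable in x and y
    dx2 = (xc[None, :] - pts[:, 0][:, None]) ** 2  # (n, nx)
    dy2 = (yc[None, :] - pts[:, 1][:, None]) ** 2  # (n, ny)
    ex = np.exp(-dx2 / (2 * h * h))
    ey = np.exp(-dy2 / (2 * h * h))
    dens = np.einsum("pi,pj->ji", ex, ey) / (len(pts) * 2 * np.pi * h * h)  # (ny, nx)
    mass = dens * c * c
    mass /= mass.sum()
    return GriddedUD(x0=float(x0), y0=float(y0), cell=c, mass=mass)


def kde95_area(ud: GriddedUD, level: float = 0.95) -> HomeRange:
    """Smallest cell set holding ``level`` of the UD mass.

    Cells are ranked by mass descending (row-major index breaks ties, for
    determinism); the shortest prefix with cumulative mass >= level is the
    home range, with area = cell count x cell².
    """
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    m = int(np.searchsorted(cum, level - 1e-12) + 1)
    m = min(m, flat.size)
    idx = order[:m]
    cells = np.column_stack(np.unravel_index(idx, ud.mass.shape))
    return HomeRange(method="kde95", area=float(m * ud.cell**2), grid=ud, cells=cells)


def kde95(points, cfg: KDEConfig = KDEConfig()) -> HomeRange:
    """Convenience: UD construction followed by the isopleth cell set."""
    return kde95_area(kde_ud(points, cfg), level=cfg.level)


def href_adhoc(points) -> float:
    """Reference ('ad hoc') bandwidth for a bivariate normal kernel:
    ``h = sqrt((var x + var y) / 2) * n^(-1/6)`` with unbiased variances."""
    pts = as_xy(points)
    n = len(pts)
    if n < 2:
        raise ValueError("bandwidth needs at least 2 points")
    s2 = 0.5 * (np.var(pts[:, 0], ddof=1) + np.var(pts[:, 1], ddof=1))
    if s2 == 0:
        raise ValueError("all points identical: bandwidth would be zero")
    return float(np.sqrt(s2) * n ** (-1.0 / 6.0))


def proportion_in_homerange(points, hr: HomeRange) -> float:
    """Fraction of points inside the home range (boundary counts as inside for
    the MCP polygon; for the kernel, a point counts when it falls in an
    occupied isopleth cell)."""
    pts = as_xy(points)
    if len(pts) == 0:
        raise ValueError("no points")
    if hr.method == "mcp95":
        poly = hr.polygon()
        geoms = shapely.points(pts[:, 0], pts[:, 1])
        inside = shapely.covers(poly, geoms)
        return float(np.mean(inside))
    if hr.method == "kde95":
        ud = hr.grid
        j = np.floor((pts[:, 0] - ud.x0) / ud.cell).astype(int)
        i = np.floor((pts[:, 1] - ud.y0) / ud.cell).astype(int)
        ny, nx = ud.mass.shape
        occupied = np.zeros((ny, nx), dtype=bool)
        occupied[hr.cells[:, 0], hr.cells[:, 1]] = True
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        inside = np.zeros(len(pts), dtype=bool)
        inside[ok] = occupied[i[ok], j[ok]]
        return float(np.mean(inside))
    raise ValueError(f"unknown home-range method {hr.method!r}")
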