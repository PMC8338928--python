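"""Kernel-density home ranges: href bandwidth, gridded KDE, isopleth areas.

The annual home range of a bird is the 95% (total range) and 50% (core)
isopleth of a bivariate-normal kernel density estimate on a 500 m grid,
with the classic "reference" bandwidth href = 0.5 (sd_x + sd_y) n^(-1/6).
Years run May to April so each season-year falls inside a single age class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .projection import LocalProjection
from .tracking import AgeWindow, Trajectory, age_class_on

logger = logging.getLogger(__name__)


def season_year(d: date) -> int:
    """Label of the May-to-April season containing a date (year of its May)."""
    return d.year if d.month >= 5 else d.year - 1


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth in metres: ``0.5 (sd_x + sd_y) n^(-1/6)``.

    Sample (n−1) standard deviations.  Raises for n < 5 or an all-identical
    point set, where a fixed bandwidth should be supplied instead.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValueError("href needs at least 5 points; supply a fixed bandwidth")
    h = 0.5 * (pts[:, 0].std(ddof=1) + pts[:, 1].std(ddof=1)) * n ** (-1.0 / 6.0)
    if h <= 0:
        raise ValueError("degenerate point set (zero spread); supply a fixed bandwidth")
    return float(h)


@dataclass
class DensityGrid:
    """Regular raster of utilisation density (per m²), normalised to 1."""

    density: np.ndarray  # (ny, nx)
    x_min: float
    y_max: float
    cell: float

    @property
    def cell_area_m2(self) -> float:
        return self.cell * self.cell

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.density.shape[1]) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.density.shape[0]) + 0.5) * self.cell

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area_m2)


def kde_grid(
    points: np.ndarray, h: float, cell_m: float = 500.0, extend_factor: float = 4.0
) -> DensityGrid:
    """Bivariate-normal KDE evaluated at cell centres.

    Equal, independent bandwidth ``h`` on both axes; the grid extends
    ``extend_factor * h`` (≥3h) beyond the data bounding box so the isopleths
    of interest fall inside it.  Values are renormalised so the discrete
    mass sums to exactly 1.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pad = extend_factor * h
    x_min = pts[:, 0].min() - pad
    x_max = pts[:, 0].max() + pad
    y_min = pts[:, 1].min() - pad
    y_max = pts[:, 1].max() + pad
    nx = max(1, int(np.ceil((x_max - x_min) / cell_m)))
    ny = max(1, int(np.ceil((y_max - y_min) / cell_m)))
    xc = x_min + (np.arange(nx) + 0.5) * cell_m
    yc = (y_min + ny * cell_m) - (np.arange(ny) + 0.5) * cell_m

    # Separable Gaussian kernel: sum over points factorises per axis.
    gx = np.exp(-0.5 * ((xc[:, None] - pts[None, :, 0]) / h) ** 2)  # (nx, n)
    gy = np.exp(-0.5 * ((yc[:, None] - pts[None, :, 1]) / h) ** 2)  # (ny, n)
    dens = (gy @ gx.T) / (2.0 * np.pi * h * h * len(pts))
    dens /= dens.sum() * cell_m * cell_m
    return DensityGrid(density=dens, x_min=x_min, y_max=y_min + ny * cell_m, cell=cell_m)


def kde_at_points(points: np.ndarray, h: float, eval_xy: np.ndarray) -> np.ndarray:
    """Exact (un-gridded) KDE value at arbitrary locations."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ev = np.atleast_2d(np.asarray(eval_xy, dtype=float))
    d2 = ((ev[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-0.5 * d2 / (h * h)).sum(axis=1) / (2.0 * np.pi * h * h * len(pts))


def isopleth_area_km2(grid: DensityGrid, level: float) -> float:
    """Area of the highest-density region holding ``level`` of the mass.

    Cells are ranked by density (descending, stable order) and accumulated
    until the target mass is reached; the area is the cell count times the
    cell area.  The minimal set is used, so ties at the boundary density are
    included only as far as needed, in scan order.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mass = (grid.density * grid.cell_area_m2).ravel()
    order = np.argsort(-mass, kind="stable")
    cum = np.cumsum(mass[order])
    n_cells = int(np.searchsorted(cum, level * cum[-1] - 1e-12) + 1)
    return n_cells * grid.cell_area_m2 / 1e6


@dataclass
class KernelHomeRange:
    bird_id: str
    season: int  # May-to-April season label (year of the May)
    age_class: str
    n_fixes: int
    bandwidth_m: float
    area_km2_95: float
    area_km2_50: float
    grid: DensityGrid | None = None


def annual_ranges(
    traj: Trajectory,
    windows: list[AgeWindow],
    cell_m: float = 500.0,
    min_fixes: int = 30,
    keep_grids: bool = False,
) -> list[KernelHomeRange]:
    """One kernel home range per May-to-April season with enough fixes.

    Seasons with fewer than ``min_fixes`` fixes are skipped with a log
    entry.  Fixes are projected per season about their own mean coordinate.
    """
    seasons = traj.fixes["timestamp"].dt.date.map(season_year)
    ranges = []
    for season, sel in traj.fixes.groupby(seasons.to_numpy()):
        if len(sel) < min_fixes:
            logger.info(
                "bird %s season %d: %d fixes < %d, skipped", traj.bird_id, season, len(sel), min_fixes
            )
            continue
        proj = LocalProjection.for_points(sel["lon"].to_numpy(), sel["lat"].to_numpy())
        xy = proj.to_planar(sel["lon"].to_numpy(), sel["lat"].to_numpy())
        h = href_bandwidth(xy)
        grid = kde_grid(xy, h, cell_m=cell_m)
        cls = age_class_on(windows, date(season, 5, 1)) or age_class_on(
            windows, sel["timestamp"].dt.date.iloc[0]
        )
        ranges.append(
            KernelHomeRange(
                bird_id=traj.bird_id,
                season=int(season),
                age_class=cls or "unknown",
                n_fixes=len(sel),
                bandwidth_m=h,
                area_km2_95=isopleth_area_km2(grid, 0.95),
                area_km2_50=isopleth_area_km2(grid, 0.50),
                grid=grid if keep_grids else None,
            )
        )
    return ranges


def cumulative_range(
    trajectories: list[Trajectory],
    windows_by_bird: dict[str, list[AgeWindow]],
    age_class: str,
    cell_m: float = 500.0,
) -> KernelHomeRange:
    """Pooled-fix kernel range across all birds of one age class."""
    frames = []
    for traj in trajectories:
        wins = windows_by_bird.get(traj.bird_id, [])
        cls = traj.fixes["timestamp"].dt.date.map(lambda d: age_class_on(wins, d))
        frames.append(traj.fixes[np.asarray(cls == age_class)])
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        raise ValueError(f"no fixes in class {age_class!r}")
    proj = LocalProjection.for_points(pooled["lon"].to_numpy(), pooled["lat"].to_numpy())
    xy = proj.to_planar(pooled["lon"].to_numpy(), pooled["lat"].to_numpy())
    h = href_bandwidth(xy)
    grid = kde_grid(xy, h, cell_m=cell_m)
    return KernelHomeRange(
        bird_id="all",
        season=-1,
        age_class=age_class,
        n_fixes=len(pooled),
        bandwidth_m=h,
        area_km2_95=isopleth_area_km2(grid, 0.95),
        area_km2_50=isopleth_area_km2(grid, 0.50),
        grid=grid,
    )


def range_summary(ranges: list[KernelHomeRange]) -> pd.DataFrame:
    """Per-class mean ± SD of 95%/50% areas (sample SD; 0 for single range)."""
    df = pd.DataFrame(
        [
            {
                "bird_id": r.bird_id,
                "season": r.season,
                "age_class": r.age_class,
                "area_km2_95": r.area_km2_95,
                "area_km2_50": r.area_km2_50,
            }
            for r in ranges
        ]
    )
    rows = []
    for cls, grp in df.groupby("age_class", sort=True):
        rows.append(
            {
                "age_class": cls,
                "n_ranges": len(grp),
                "mean_km2_95": float(grp["area_km2_95"].mean()),
                "sd_km2_95": float(grp["area_km2_95"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "mean_km2_50": float(grp["area_km2_50"].mean()),
                "sd_km2_50": float(grp["area_km2_50"].std(ddof=1)) if len(grp) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
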