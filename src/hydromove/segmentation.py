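"""Residence-area segmentation of a trajectory.

Within an analysis window every tracked day is labelled Moving (effective
displacement strictly greater than the threshold) or Staying; maximal runs
of at least two consecutive Staying days become candidate residence Areas.
Because a bird can make a large move yet return to the same place, the 95%
MCPs of consecutive candidates are compared: overlapping polygons are merged
into one Area (the bird never really left), disjoint ones stay separate.
Merging is applied left-to-right and repeated until stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .mcp import Mcp, mcp_95, mcps_overlap
from .movement import MovingDayThreshold
from .projection import LocalProjection
from .tracking import AgeWindow, Trajectory, age_class_on


@dataclass
class ResidenceArea:
    """A multi-day occupancy segment with its 95% MCP."""

    bird_id: str
    area_id: int
    start_date: date
    end_date: date
    fixes: pd.DataFrame  # timestamp, lon, lat, plus planar x, y
    mcp: Mcp

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def dates(self) -> list[date]:
        return sorted(set(self.fixes["timestamp"].dt.date))


@dataclass
class SegmentationResult:
    bird_id: str
    areas: list[ResidenceArea]
    moving_days: list[date]
    merge_log: list[dict] = field(default_factory=list)
    discarded_runs: list[dict] = field(default_factory=list)
    threshold_km: float = float("nan")
    projection: LocalProjection | None = None


def label_moving_days(daily: pd.DataFrame, threshold_km: float) -> pd.DataFrame:
    """Label each day Moving/Staying.

    A day exactly at the threshold is a Staying day: moving means displacing
    strictly more than the threshold distance.
    """
    out = daily.copy()
    out["is_moving"] = out["effective_distance_km"] > threshold_km
    return out


def _runs_of_staying(labelled: pd.DataFrame) -> list[list[date]]:
    """Maximal runs of consecutive (calendar-contiguous) Staying days."""
    runs: list[list[date]] = []
    current: list[date] = []
    for _, row in labelled.sort_values("date", kind="stable").iterrows():
        d = row["date"]
        if row["is_moving"]:
            if current:
                runs.append(current)
            current = []
            continue
        if current and (d - current[-1]).days != 1:
            runs.append(current)
            current = []
        current.append(d)
    if current:
        runs.append(current)
    return runs


def _build_area(
    bird_id: str, fixes: pd.DataFrame, proj: LocalProjection, retain: float
) -> ResidenceArea:
    fixes = fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)
    xy = proj.to_planar(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    fixes = fixes.assign(x=xy[:, 0], y=xy[:, 1])
    dates = fixes["timestamp"].dt.date
    return ResidenceArea(
        bird_id=bird_id,
        area_id=-1,
        start_date=min(dates),
        end_date=max(dates),
        fixes=fixes,
        mcp=mcp_95(xy, retain=retain),
    )


def segment_areas(
    daily: pd.DataFrame,
    traj: Trajectory,
    threshold: MovingDayThreshold | float,
    window: tuple[date, date],
    retain: float = 0.95,
    overlap_buffer_m: float = 500.0,
    projection: LocalProjection | None = None,
) -> SegmentationResult:
    """Partition one bird's window into residence Areas and Moving Days.

    ``daily`` is the output of :func:`hydromove.movement.daily_movements`
    for this bird; ``window`` is an inclusive date range.  Runs of fewer
    than two staying days are discarded (and logged); consecutive candidate
    areas whose 95% MCPs intersect are merged, cascading left-to-right until
    no merge applies.
    """
    thr_km = threshold.threshold_km if isinstance(threshold, MovingDayThreshold) else float(threshold)
    w0, w1 = window
    day_in = daily[(daily["bird_id"] == traj.bird_id)]
    day_in = day_in[(day_in["date"] >= w0) & (day_in["date"] <= w1)]
    fix_dates = traj.local_dates()
    fixes_in = traj.fixes[(fix_dates >= w0) & (fix_dates <= w1)]
    if day_in.empty or fixes_in.empty:
        return SegmentationResult(traj.bird_id, [], [], threshold_km=thr_km)

    if projection is None:
        projection = LocalProjection.for_points(
            fixes_in["lon"].to_numpy(), fixes_in["lat"].to_numpy()
        )

    labelled = label_moving_days(day_in, thr_km)
    moving = sorted(labelled.loc[labelled["is_moving"], "date"])
    runs = _runs_of_staying(labelled)

    result = SegmentationResult(
        traj.bird_id, [], moving, threshold_km=thr_km, projection=projection
    )
    candidates: list[ResidenceArea] = []
    dates_all = fixes_in["timestamp"].dt.date
    for run in runs:
        if len(run) < 2:
            result.discarded_runs.append({"dates": run, "reason": "run shorter than 2 days"})
            continue
        sel = fixes_in[dates_all.isin(run)]
        candidates.append(_build_area(traj.bird_id, sel, projection, retain))

    # Left-to-right merge cascade until stable.
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(candidates) - 1:
            a, b = candidates[i], candidates[i + 1]
            overlap = mcps_overlap(a.mcp, b.mcp, buffer_m=overlap_buffer_m)
            result.merge_log.append(
                {
                    "left": (a.start_date, a.end_date),
                    "right": (b.start_date, b.end_date),
                    "merged": overlap,
                }
            )
            if overlap:
                merged_fixes = pd.concat(
                    [a.fixes[["timestamp", "lon", "lat"]], b.fixes[["timestamp", "lon", "lat"]]],
                    ignore_index=True,
                )
                candidates[i : i + 2] = [
                    _build_area(traj.bird_id, merged_fixes, projection, retain)
                ]
                changed = True
            else:
                i += 1

    for k, area in enumerate(candidates, start=1):
        area.area_id = k
    result.areas = candidates
    return result


def stay_durations(
    results: list[SegmentationResult] | SegmentationResult,
    age_windows: dict[str, list[AgeWindow]] | None = None,
) -> pd.DataFrame:
    """Mean +- SD (sample, n-1) of residence durations, grouped by age class.

    An area's class is the class in effect on its start date; without age
    windows all areas are pooled under class ``all``.  Groups with a single
    area report SD 0 with ``sd_degenerate`` set.
    """
    if isinstance(results, SegmentationResult):
        results = [results]
    rows = []
    for res in results:
        for area in res.areas:
            cls = "all"
            if age_windows is not None:
                cls = age_class_on(age_windows.get(area.bird_id, []), area.start_date) or "unknown"
            rows.append({"age_class": cls, "duration_days": area.duration_days})
    if not rows:
        return pd.DataFrame(
            columns=["age_class", "n_areas", "mean_days", "sd_days", "sd_degenerate"]
        )
    df = pd.DataFrame(rows)
    out = []
    for cls, grp in df.groupby("age_class", sort=True):
        n = len(grp)
        out.append(
            {
                "age_class": cls,
                "n_areas": n,
                "mean_days": float(grp["duration_days"].mean()),
                "sd_days": float(grp["duration_days"].std(ddof=1)) if n > 1 else 0.0,
                "sd_degenerate": n == 1,
            }
        )
    return pd.DataFrame(out)


def areas_to_geojson(results: list[SegmentationResult]) -> dict:
    """GeoJSON FeatureCollection of area MCPs (lon/lat coordinates)."""
    from shapely.geometry import mapping
    from shapely.ops import transform as shp_transform

    features = []
    for res in results:
        proj = res.projection
        for area in res.areas:
            geom = area.mcp.polygon
            if proj is not None:
                geom = shp_transform(
                    lambda x, y: tuple(proj.to_lonlat(x, y).T), geom
                )
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "bird_id": area.bird_id,
                        "area_id": area.area_id,
                        "start_date": area.start_date.isoformat(),
                        "end_date": area.end_date.isoformat(),
                        "duration_days": area.duration_days,
                        "degenerate_mcp": area.mcp.degenerate,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
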