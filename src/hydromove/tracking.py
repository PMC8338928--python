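"""Reading, validating, filtering and age-classifying GPS tracking data.

The tracking schedule is one fix per hour between 06:00 and 18:00 local time
(UTC+02:00, the activity period of the birds).  Timestamps are stored with
that fixed offset and calendar "days" are local midnights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: Fixed UTC offset of the fix schedule (GMT+2).
FIX_TZ = timezone(timedelta(hours=2))

#: Default CSV column names; override with ``column_map`` for other layouts
#: (e.g. Movebank exports).
DEFAULT_COLUMN_MAP = {
    "bird_id": "bird_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}

AgeClass = Literal["juvenile", "immature", "adult"]


@dataclass
class Trajectory:
    """Time-ordered GPS fixes for one bird.

    ``fixes`` has columns ``timestamp`` (tz-aware, +02:00), ``lon``, ``lat``.
    """

    bird_id: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        self.fixes = self.fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def start_date(self) -> date:
        return self.fixes["timestamp"].iloc[0].date()

    @property
    def end_date(self) -> date:
        return self.fixes["timestamp"].iloc[-1].date()

    def local_dates(self) -> pd.Series:
        """Local calendar date of every fix."""
        return self.fixes["timestamp"].dt.date


@dataclass
class ReadReport:
    n_rows: int = 0
    n_rejected: int = 0
    n_duplicates: int = 0
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass(frozen=True)
class AgeWindow:
    """One contiguous age-class interval of a bird's tracking period."""

    bird_id: str
    age_class: AgeClass
    start_date: date
    end_date: date

    def contains(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


def read_fixes(path, column_map: dict | None = None) -> tuple[list[Trajectory], ReadReport]:
    """Read a delimited-text fix file into one :class:`Trajectory` per bird.

    Rows with unparseable timestamps/coordinates or out-of-range coordinates
    are rejected and counted; duplicate timestamps within a bird keep the
    first row.  A missing mandatory column raises ``ValueError``; an empty
    file yields an empty collection with a warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in cmap.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    report = ReadReport(n_rows=len(raw))
    if raw.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return [], report

    df = pd.DataFrame(
        {
            "bird_id": raw[cmap["bird_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[cmap["timestamp"]], errors="coerce", utc=True),
            "lon": pd.to_numeric(raw[cmap["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[cmap["lat"]], errors="coerce"),
        }
    )
    reasons = pd.Series("", index=df.index)
    reasons[df["timestamp"].isna()] = "bad timestamp"
    reasons[df["lon"].isna() | df["lat"].isna()] = "bad coordinate"
    oob = (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    reasons[oob.fillna(False)] = "coordinate out of range"
    bad = reasons != ""
    if bad.any():
        rej = raw[bad].copy()
        rej["reason"] = reasons[bad]
        report.rejects = rej
        report.n_rejected = int(bad.sum())
    df = df[~bad]
    df["timestamp"] = df["timestamp"].dt.tz_convert(FIX_TZ)

    trajectories: list[Trajectory] = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        dup = grp["timestamp"].duplicated(keep="first")
        if dup.any():
            warnings.warn(
                f"bird {bird_id}: dropped {int(dup.sum())} duplicate timestamp(s)",
                stacklevel=2,
            )
            report.n_duplicates += int(dup.sum())
            grp = grp[~dup]
        trajectories.append(Trajectory(bird_id, grp[["timestamp", "lon", "lat"]]))
    return trajectories, report


def write_fixes(trajectories: Iterable[Trajectory], path) -> None:
    """Write trajectories back to CSV, ISO-8601 timestamps with offset."""
    frames = []
    for traj in trajectories:
        out = traj.fixes.copy()
        out.insert(0, "bird_id", traj.bird_id)
        out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
        frames.append(out)
    all_rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["bird_id", "timestamp", "lon", "lat"])
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    all_rows.to_csv(path, index=False, float_format="%.10g")


def filter_speed_outliers(
    traj: Trajectory, max_kmh: float = 150.0
) -> tuple[Trajectory, pd.DataFrame]:
    """Drop fixes implying unrealistic flight speed.

    Sequential-greedy pass: each fix is compared against the last *retained*
    fix; if the implied great-circle speed exceeds ``max_kmh`` the fix is
    removed.  Greedy filtering is deterministic and idempotent.
    """
    from .movement import great_circle_km

    fixes = traj.fixes
    if len(fixes) <= 1:
        return traj, fixes.iloc[0:0]
    ts = fixes["timestamp"].to_numpy()
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    keep = [0]
    removed_idx = []
    for i in range(1, len(fixes)):
        j = keep[-1]
        dt_h = (ts[i] - ts[j]) / np.timedelta64(1, "h")
        d_km = great_circle_km(lon[j], lat[j], lon[i], lat[i])
        if dt_h > 0 and d_km / dt_h > max_kmh:
            removed_idx.append(i)
        else:
            keep.append(i)
    removed = fixes.iloc[removed_idx]
    return Trajectory(traj.bird_id, fixes.iloc[keep]), removed


def exclude_fixes(traj: Trajectory, exclude_idx: Iterable[int]) -> Trajectory:
    """Drop user-flagged fixes (stand-in for manual track inspection)."""
    idx = sorted(set(int(i) for i in exclude_idx))
    return Trajectory(traj.bird_id, traj.fixes.drop(index=idx, errors="raise"))


def _first_may_after(d: date) -> date:
    m = date(d.year, 5, 1)
    return m if m > d else date(d.year + 1, 5, 1)


def assign_age_windows(
    traj: Trajectory,
    tagging_date: date,
    tagging_class: AgeClass = "juvenile",
) -> list[AgeWindow]:
    """Partition the tracking span into juvenile / immature / adult windows.

    Birds tagged as juveniles remain juvenile until the first 1 May after
    tagging (the start of the next breeding season), are immature for the
    two following May-to-May years, and adult from the fourth year onward.
    A bird tagged as an adult is adult throughout.  Windows are clipped to
    the tracking span; the concatenated windows tile it exactly.
    """
    if tagging_class not in ("juvenile", "adult"):
        raise ValueError("tagging_class must be 'juvenile' or 'adult'")
    start, end = traj.start_date, traj.end_date
    if tagging_class == "adult":
        return [AgeWindow(traj.bird_id, "adult", start, end)]
    may1 = _first_may_after(tagging_date)
    imm_end = date(may1.year + 2, 4, 30)
    bounds = [
        ("juvenile", date.min, may1 - timedelta(days=1)),
        ("immature", may1, imm_end),
        ("adult", imm_end + timedelta(days=1), date.max),
    ]
    windows = []
    for cls, lo, hi in bounds:
        lo2, hi2 = max(lo, start), min(hi, end)
        if lo2 <= hi2:
            windows.append(AgeWindow(traj.bird_id, cls, lo2, hi2))
    return windows


def age_class_on(windows: Iterable[AgeWindow], d: date) -> AgeClass | None:
    """Age class in effect on a date, or ``None`` outside all windows."""
    for w in windows:
        if w.contains(d):
            return w.age_class
    return None
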