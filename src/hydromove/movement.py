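"""Daily displacement metrics and the Moving-Day threshold.

The daily movement summary is the maximum great-circle distance between any
two fixes of a calendar day.  Overnight movements (last fix of day *d* to
first fix of day *d*+1) are allocated to day *d*, so a bird that relocates
after dark is credited with that displacement on the day it left.  The
Moving-Day threshold is the smallest rounded distance capturing a target
fraction (default 80%) of daily movements; days above it are "Moving Days".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import EARTH_RADIUS_KM
from .tracking import AgeWindow, Trajectory, age_class_on

#: Reporting order of months: the biological year starts with the breeding
#: season in May.
MONTH_ORDER = [5, 6, 7, 8, 9, 10, 11, 12, 1, 2, 3, 4]

DAILY_COLUMNS = [
    "bird_id",
    "date",
    "n_fixes",
    "max_daily_distance_km",
    "night_distance_km",
    "effective_distance_km",
]


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle (haversine) distance in km on a sphere of R=6371.0088 km.

    Accepts scalars or broadcastable arrays; symmetric and non-negative.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return d if d.ndim else float(d)


def _max_pairwise_km(lon: np.ndarray, lat: np.ndarray) -> float:
    if len(lon) < 2:
        return 0.0
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    return float(np.max(d))


@dataclass(frozen=True)
class MovingDayThreshold:
    """Distance threshold separating Staying from Moving days."""

    quantile_level: float
    threshold_km: float
    achieved_coverage: float
    n_days: int


def daily_movements(traj: Trajectory) -> pd.DataFrame:
    """Per-day displacement summary for one bird.

    Returns one row per calendar day with at least one fix (days without
    data produce no row: absence of data is not absence of movement), with
    columns ``bird_id, date, n_fixes, max_daily_distance_km,
    night_distance_km, effective_distance_km``.  ``night_distance_km`` is
    the distance from the previous day's last fix to this day's first fix
    (0 unless the previous calendar day has fixes); it is allocated to the
    *previous* day's effective distance.
    """
    fixes = traj.fixes
    dates = traj.local_dates().to_numpy()
    rows = []
    for d in pd.unique(dates):
        sel = fixes[dates == d]
        rows.append(
            {
                "bird_id": traj.bird_id,
                "date": d,
                "n_fixes": len(sel),
                "first_lon": sel["lon"].iloc[0],
                "first_lat": sel["lat"].iloc[0],
                "last_lon": sel["lon"].iloc[-1],
                "last_lat": sel["lat"].iloc[-1],
                "max_daily_distance_km": _max_pairwise_km(
                    sel["lon"].to_numpy(), sel["lat"].to_numpy()
                ),
            }
        )
    daily = pd.DataFrame(rows).sort_values("date", kind="stable").reset_index(drop=True)

    night = np.zeros(len(daily))
    consecutive = np.zeros(len(daily), dtype=bool)
    for i in range(1, len(daily)):
        if (daily["date"].iloc[i] - daily["date"].iloc[i - 1]).days == 1:
            consecutive[i] = True
            night[i] = great_circle_km(
                daily["last_lon"].iloc[i - 1],
                daily["last_lat"].iloc[i - 1],
                daily["first_lon"].iloc[i],
                daily["first_lat"].iloc[i],
            )
    daily["night_distance_km"] = night

    # Night movement between day d and d+1 counts toward day d.
    effective = daily["max_daily_distance_km"].to_numpy().copy()
    for i in range(1, len(daily)):
        if consecutive[i]:
            effective[i - 1] = max(effective[i - 1], night[i])
    daily["effective_distance_km"] = effective
    return daily[DAILY_COLUMNS]


def fit_moving_threshold(
    daily: pd.DataFrame, level: float = 0.80, rounding_km: float = 1.0
) -> MovingDayThreshold:
    """Smallest multiple of ``rounding_km`` below which a fraction ``level``
    of daily effective distances fall.

    The threshold is rounded (default whole km) because it is meant as an
    interpretable field rule, not an exact empirical quantile; the achieved
    coverage is reported alongside.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d = np.asarray(daily["effective_distance_km"], dtype=float)
    if len(d) < 10:
        raise ValueError("need at least 10 days to fit a movement threshold")
    k = 1
    while True:
        thr = k * rounding_km
        coverage = float(np.mean(d < thr))
        if coverage >= level:
            return MovingDayThreshold(level, thr, coverage, len(d))
        k += 1


def monthly_mean_max_distance(
    daily: pd.DataFrame, age_windows: list[AgeWindow]
) -> pd.DataFrame:
    """Mean effective daily distance per bird x age class x calendar month.

    Months are ordered May -> April so summaries start at the beginning of
    the breeding season.
    """
    df = daily.copy()
    df["age_class"] = [age_class_on(age_windows, d) for d in df["date"]]
    df = df[df["age_class"].notna()]
    df["month"] = [d.month for d in df["date"]]
    out = (
        df.groupby(["bird_id", "age_class", "month"], sort=False)["effective_distance_km"]
        .mean()
        .reset_index()
        .rename(columns={"effective_distance_km": "mean_effective_km"})
    )
    out["month"] = pd.Categorical(out["month"], categories=MONTH_ORDER, ordered=True)
    return out.sort_values(["bird_id", "age_class", "month"], kind="stable").reset_index(
        drop=True
    )
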