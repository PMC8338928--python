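"""NDWI surface-water composites and daily sampling at bird positions.

NDWI = (Green − NIR) / (Green + NIR): +1 marks open water, −1 dry land.
The index is consumed as 8-day composites (matching the cadence of MODIS
surface-reflectance products); a composite is usable only when at least 92%
of its pixels are good quality and at most 2% are unclassified.  The daily
mean NDWI of a bird-day is the mean of nearest-cell values at that day's
positions, which keeps the per-pixel classification semantics (no
interpolation across land/water boundaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .projection import LocalProjection
from .rasters import Raster
from .segmentation import ResidenceArea

logger = logging.getLogger(__name__)

COMPOSITE_DAYS = 8

Phase = Literal["presence", "post_abandonment", "pre_abandonment_week", "post_arrival_week"]


def ndwi(green, nir):
    """McFeeters water index, applied element-wise.

    Requires non-negative reflectances; cells with ``green + nir == 0`` are
    undefined and return NaN (missing), never 0.
    """
    green = np.asarray(green, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.nanmin(green) < 0 or np.nanmin(nir) < 0:
        raise ValueError("reflectances must be non-negative")
    denom = green + nir
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (green - nir) / denom, np.nan)
    return out if out.ndim else float(out)


@dataclass
class NdwiComposite:
    """One 8-day NDWI layer, half-open date window [start, start + 8 d)."""

    window_start: date
    raster: Raster
    frac_good: float = 1.0
    frac_unclassified: float = 0.0

    @property
    def window_end(self) -> date:
        return self.window_start + timedelta(days=COMPOSITE_DAYS)

    def covers(self, d: date) -> bool:
        return self.window_start <= d < self.window_end


@dataclass
class NdwiSample:
    bird_id: str
    date: date
    area_id: int
    phase: Phase
    daily_mean_ndwi: float
    n_positions: int = 0


def qc_screen(
    comp: NdwiComposite, min_good: float = 0.92, max_unclassified: float = 0.02
) -> bool:
    """Composite usability rule; bounds inclusive."""
    return comp.frac_good >= min_good and comp.frac_unclassified <= max_unclassified


def composite_for(
    composites: Sequence[NdwiComposite], d: date, qc: bool = True
) -> NdwiComposite | None:
    """The QC-passing composite whose half-open window contains a date."""
    for comp in composites:
        if comp.covers(d) and (not qc or qc_screen(comp)):
            return comp
    return None


def sample_daily_mean(points_xy: np.ndarray, comp: NdwiComposite) -> tuple[float, int]:
    """Mean NDWI over sampled positions (missing cells dropped).

    Returns ``(mean, n_valid)``; mean is NaN when every cell is missing or
    out of extent.
    """
    vals = comp.raster.sample_nearest(points_xy)
    n_out = int(np.sum(~comp.raster.cell_index(points_xy)[2]))
    if n_out:
        logger.warning("%d position(s) outside raster extent dropped", n_out)
    valid = vals[~np.isnan(vals)]
    if len(valid) == 0:
        return float("nan"), 0
    return float(valid.mean()), int(len(valid))


def phase_samples(
    area: ResidenceArea,
    composites: Sequence[NdwiComposite],
    projection: LocalProjection,
    post_days: int = 7,
    week_days: int = 7,
    skipped: list | None = None,
) -> list[NdwiSample]:
    """Daily mean NDWI samples for every analysis phase of one Area.

    * ``presence`` — one sample per occupied day from that day's own fixes;
    * ``pre_abandonment_week`` / ``post_arrival_week`` — the presence
      samples of the last / first ``week_days`` occupied days (all days for
      shorter stays);
    * ``post_abandonment`` — for each of the ``post_days`` days after the
      area's end date, the full set of occupancy fix locations re-evaluated
      on the composite covering that later day (the bird is gone, so the
      occupied locations themselves are re-sampled).

    Days whose covering composite is missing or fails QC are skipped and
    logged.
    """
    if skipped is None:
        skipped = []
    fixes = area.fixes
    xy_all = projection.to_planar(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    fix_dates = fixes["timestamp"].dt.date.to_numpy()
    occupied = area.dates

    presence: dict[date, NdwiSample] = {}
    for d in occupied:
        comp = composite_for(composites, d)
        if comp is None:
            skipped.append({"bird_id": area.bird_id, "date": d, "phase": "presence",
                            "reason": "no usable composite"})
            continue
        mean, n = sample_daily_mean(xy_all[fix_dates == d], comp)
        if np.isnan(mean):
            skipped.append({"bird_id": area.bird_id, "date": d, "phase": "presence",
                            "reason": "all cells missing"})
            continue
        presence[d] = NdwiSample(area.bird_id, d, area.area_id, "presence", mean, n)

    samples: list[NdwiSample] = list(presence.values())

    def _relabel(days: Iterable[date], phase: Phase) -> None:
        for d in days:
            if d in presence:
                s = presence[d]
                samples.append(
                    NdwiSample(s.bird_id, s.date, s.area_id, phase, s.daily_mean_ndwi, s.n_positions)
                )

    week = min(week_days, len(occupied))
    _relabel(occupied[-week:], "pre_abandonment_week")
    _relabel(occupied[:week], "post_arrival_week")

    for k in range(1, post_days + 1):
        d = area.end_date + timedelta(days=k)
        comp = composite_for(composites, d)
        if comp is None:
            skipped.append({"bird_id": area.bird_id, "date": d, "phase": "post_abandonment",
                            "reason": "no usable composite"})
            continue
        mean, n = sample_daily_mean(xy_all, comp)
        if np.isnan(mean):
            skipped.append({"bird_id": area.bird_id, "date": d, "phase": "post_abandonment",
                            "reason": "all cells missing"})
            continue
        samples.append(NdwiSample(area.bird_id, d, area.area_id, "post_abandonment", mean, n))
    return samples


def samples_to_frame(samples: Iterable[NdwiSample]) -> pd.DataFrame:
    rows = [
        {
            "bird_id": s.bird_id,
            "date": s.date,
            "area_id": s.area_id,
            "phase": s.phase,
            "daily_mean_ndwi": s.daily_mean_ndwi,
            "n_positions": s.n_positions,
        }
        for s in samples
    ]
    return pd.DataFrame(
        rows,
        columns=["bird_id", "date", "area_id", "phase", "daily_mean_ndwi", "n_positions"],
    )
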