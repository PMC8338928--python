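from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from hydromove.projection import LocalProjection
from hydromove.tracking import FIX_TZ, Trajectory


def make_trajectory(bird_id, rows):
    """Trajectory from (year, month, day, hour, lon, lat) tuples."""
    fixes = pd.DataFrame(
        {
            "timestamp": [datetime(y, m, d, h, tzinfo=FIX_TZ) for y, m, d, h, _, _ in rows],
            "lon": [r[4] for r in rows],
            "lat": [r[5] for r in rows],
        }
    )
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    return Trajectory(bird_id, fixes)


@pytest.fixture
def origin_projection():
    return LocalProjection(lon0=30.0, lat0=-12.0)


def planar_trajectory(bird_id, day_specs, proj, rng, scatter_m=300.0, year=2014, month=10):
    """Trajectory with 13 hourly fixes/day scattered around planar centroids.

    ``day_specs`` maps day-of-month to an (x, y) centroid in metres, or to a
    pair of centroids ((x1, y1), (x2, y2)) for a relocation day (morning
    fixes at the first, afternoon fixes at the second).
    """
    rows = []
    for day, spec in day_specs.items():
        morning = afternoon = spec
        if isinstance(spec[0], tuple):
            morning, afternoon = spec
        for h in range(6, 19):
            cx, cy = morning if h < 12 else afternoon
            x = cx + rng.normal(0, scatter_m)
            y = cy + rng.normal(0, scatter_m)
            lon, lat = proj.to_lonlat(x, y)[0]
            rows.append((year, month, day, h, lon, lat))
    return make_trajectory(bird_id, rows)
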