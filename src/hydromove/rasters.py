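"""Minimal regular-grid raster container with nearest-cell sampling.

Rasters live in the same local planar coordinate system as the trajectory
analysis (metres).  Cell (i, j) has its centre at
``(x_min + (j + 0.5) * cell, y_max - (i + 0.5) * cell)``; nodata is NaN.
Files are written as single-band float32 TIFF with a JSON sidecar carrying
the geotransform, which keeps the adapter dependency-light; converting
satellite products (e.g. MODIS HDF composites) into this layout is outside
the package boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Raster:
    values: np.ndarray  # (ny, nx) float32, NaN = nodata
    x_min: float
    y_max: float
    cell: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.ny) + 0.5) * self.cell

    def cell_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/column of each point plus an in-bounds mask."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        j = np.floor((xy[:, 0] - self.x_min) / self.cell).astype(int)
        i = np.floor((self.y_max - xy[:, 1]) / self.cell).astype(int)
        ok = (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)
        return i, j, ok

    def sample_nearest(self, xy: np.ndarray) -> np.ndarray:
        """Nearest-cell value at each point; NaN outside the extent."""
        i, j, ok = self.cell_index(xy)
        out = np.full(len(i), np.nan)
        out[ok] = self.values[i[ok], j[ok]]
        return out

    def to_file(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, self.values)
        meta = {"x_min": self.x_min, "y_max": self.y_max, "cell": self.cell,
                "crs": "local equirectangular metres"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "Raster":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = tifffile.imread(path)
        return cls(values=values, x_min=meta["x_min"], y_max=meta["y_max"], cell=meta["cell"])
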