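"""Planar-grid raster containers and light TIFF/CSV I/O.

All rasters are numpy arrays on a planar grid of square pixels (default
30 m), row 0 at the top.  Pixel (i, j) has its center at
``x = (j + 0.5) * pixel_size``, ``y = (i + 0.5) * pixel_size``; every metric
threshold in the pipeline (150 m bridging, 1/2/5 km vicinities, 25 km kernel
cutoff) is interpreted in meters on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Band order used throughout the package.
BANDS = ("blue", "green", "red", "nir", "swirs", "swirl")
BLUE, GREEN, RED, NIR, SWIRS, SWIRL = range(6)


@dataclass(frozen=True)
class GridSpec:
    """Shape and pixel size of the planar analysis grid."""

    height: int
    width: int
    pixel_size: float = 30.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def pixel_area(self) -> float:
        """Pixel area in square meters (900 m² at 30-m pixels)."""
        return self.pixel_size**2

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n, 2) array of (x, y) centers for the given pixel indices."""
        x = (np.asarray(cols) + 0.5) * self.pixel_size
        y = (np.asarray(rows) + 0.5) * self.pixel_size
        return np.column_stack([x, y])


@dataclass
class SceneStack:
    """One year of dated multiband surface-reflectance observations.

    ``reflectance`` has shape (T, H, W, 6) in the :data:`BANDS` order,
    ``days`` is day-of-year per scene, and ``sensor_tags`` carries the sensor
    identifier per scene (e.g. ``"L5"``) used by the stripe quality filter.
    """

    reflectance: np.ndarray
    days: np.ndarray
    year: int
    sensor_tags: np.ndarray = field(default=None)  # type: ignore[assignment]
    grid: GridSpec = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float32)
        self.days = np.asarray(self.days, dtype=np.int32)
        if self.reflectance.ndim != 4 or self.reflectance.shape[-1] != len(BANDS):
            raise ValueError("reflectance must have shape (T, H, W, 6)")
        if len(self.days) != self.reflectance.shape[0]:
            raise ValueError("days length must match number of scenes")
        if self.sensor_tags is None:
            self.sensor_tags = np.array(["L8"] * len(self.days))
        else:
            self.sensor_tags = np.asarray(self.sensor_tags)
        if self.grid is None:
            _, h, w, _ = self.reflectance.shape
            self.grid = GridSpec(h, w)

    @property
    def n_scenes(self) -> int:
        return int(self.reflectance.shape[0])


def write_raster(path, array: np.ndarray) -> None:
    """Write a 2-D or 3-D array as a (multi-band) TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(array))


def read_raster(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path))
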