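"""Active-fire fusion: rasterization, Voronoi dating, pixel appending and
year relocation.

Thermal-anomaly detections (MODIS-like ~1000-m footprints or VIIRS-like
~375-m footprints, a per-record attribute) complement the reflectance-based
burned-area map: they paint date rasters, reassign per-pixel burn dates by
nearest detection, append adjacent detected pixels not dominated by water,
and relocate late-season detections that surfaced spectrally only in the
following year.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from peatfire.raster import GridSpec

QUEEN = np.ones((3, 3), dtype=bool)

WATER_DOMINANCE = 0.80
RELOCATE_MAX_DIST_M = 5000.0

REQUIRED_COLUMNS = ("x", "y", "day", "year", "along_track_m", "cross_track_m")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"active-fire table missing columns: {missing}")
    return records


def rasterize_active_fires(records: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Paint each record's footprint rectangle onto a day raster.

    A pixel is covered when its center lies inside the rectangle of
    half-extents (along_track/2, cross_track/2) centered on (x, y); the
    along-track extent spans x (columns) and the cross-track extent spans y
    (rows).  Overlapping records keep the earliest day.  Returns a float
    raster of day-of-year with NaN where no fire was detected.
    """
    _check_records(records)
    px = grid.pixel_size
    out = np.full(grid.shape, np.inf)
    n_skipped = 0
    for rec in records.sort_values("day", kind="stable").itertuples():
        if not (0 <= rec.x <= grid.width * px and 0 <= rec.y <= grid.height * px):
            n_skipped += 1
            continue
        half_x, half_y = rec.along_track_m / 2.0, rec.cross_track_m / 2.0
        # pixel j has center (j + 0.5) * px
        j0 = int(np.ceil((rec.x - half_x) / px - 0.5))
        j1 = int(np.floor((rec.x + half_x) / px - 0.5))
        i0 = int(np.ceil((rec.y - half_y) / px - 0.5))
        i1 = int(np.floor((rec.y + half_y) / px - 0.5))
        i0, i1 = max(i0, 0), min(i1, grid.height - 1)
        j0, j1 = max(j0, 0), min(j1, grid.width - 1)
        if i0 > i1 or j0 > j1:
            continue
        block = out[i0:i1 + 1, j0:j1 + 1]
        np.minimum(block, rec.day, out=block)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} out-of-bounds active-fire records")
    out[np.isinf(out)] = np.nan
    return out


def assign_dates_voronoi(burned: np.ndarray, records: pd.DataFrame,
                         grid: GridSpec, fallback_day: np.ndarray | None = None,
                         tie_tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Assign each burned pixel the day of its nearest active-fire record.

    Nearest is Euclidean between the pixel center and record locations
    (Voronoi cells); distance ties take the earlier day.  When the year has
    no records, pixels keep ``fallback_day`` (the composite date) and are
    flagged low-confidence.  Returns (day raster, confident mask).
    """
    burned = np.asarray(burned, dtype=bool)
    day = np.full(grid.shape, np.nan)
    confident = np.zeros(grid.shape, dtype=bool)
    rr, cc = np.nonzero(burned)
    if rr.size == 0:
        return day, confident
    if len(records) == 0:
        if fallback_day is not None:
            day[rr, cc] = np.asarray(fallback_day, dtype=float)[rr, cc]
        return day, confident
    _check_records(records)
    pts = records[["x", "y"]].to_numpy(dtype=float)
    days = records["day"].to_numpy(dtype=float)
    tree = cKDTree(pts)
    centers = grid.pixel_centers(rr, cc)
    k = min(len(records), 8)
    dist, idx = tree.query(centers, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    near = dist <= (dist[:, [0]] + tie_tol)
    assigned = np.where(near, days[idx], np.inf).min(axis=1)
    day[rr, cc] = assigned
    confident[rr, cc] = True
    return day, confident


def append_af_pixels(burned: np.ndarray, af_day: np.ndarray,
                     water_cover: np.ndarray,
                     water_threshold: float = WATER_DOMINANCE) -> np.ndarray:
    """Append active-fire pixels Queen-connected to existing patches.

    Applied iteratively to a fixed point so chains of detections attach;
    pixels whose annual water-cover fraction is at or above the dominance
    threshold (80%) are never appended.  Output is a superset of the input.
    """
    burned = np.asarray(burned, dtype=bool)
    candidates = np.isfinite(af_day) & (np.asarray(water_cover) < water_threshold)
    return ndimage.binary_dilation(
        burned, structure=QUEEN, iterations=0, mask=candidates | burned)


def relocate_year(burned: np.ndarray, records_prev: pd.DataFrame,
                  records_current: pd.DataFrame, grid: GridSpec,
                  max_dist_m: float = RELOCATE_MAX_DIST_M) -> np.ndarray:
    """Mask of burned pixels to reassign to the previous year.

    A pixel detected in year t moves to t-1 iff (1) some previous-year
    active fire lies within 5 km (inclusive) and (2) the distance to the
    nearest previous-year fire is strictly smaller than the distance to the
    nearest current-year fire.
    """
    burned = np.asarray(burned, dtype=bool)
    out = np.zeros(grid.shape, dtype=bool)
    rr, cc = np.nonzero(burned)
    if rr.size == 0 or len(records_prev) == 0:
        return out
    centers = grid.pixel_centers(rr, cc)
    d_prev = cKDTree(
        _check_records(records_prev)[["x", "y"]].to_numpy(float)).query(centers)[0]
    if len(records_current):
        d_cur = cKDTree(
            _check_records(records_current)[["x", "y"]].to_numpy(float)
        ).query(centers)[0]
    else:
        d_cur = np.full(rr.size, np.inf)
    move = (d_prev <= max_dist_m) & (d_prev < d_cur)
    out[rr[move], cc[move]] = True
    return out
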