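"""Area-conserving peatland downscaling and peat-fire attribution.

A coarse peatland-area map (PEATMAP-like, with cells or irregular labeled
regions) is downscaled to the fine analysis grid using a continuous
peatland-plausibility index: within each coarse unit, the highest-index
fine pixels are selected until their cumulative area matches the coarse
peat area.  Burned pixels falling on the resulting mask are peat fires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from peatfire.raster import GridSpec


@dataclass
class PeatIndexMap:
    """Fine peatland-plausibility index plus coarse peat areas per unit.

    ``index`` is a [0, 1] raster; ``unit_labels`` assigns every fine pixel
    to a coarse unit (any integer labeling — rectangular cells or irregular
    regions); ``unit_area_m2`` maps unit label to its peat area in m².
    """

    index: np.ndarray
    unit_labels: np.ndarray
    unit_area_m2: dict[int, float]
    grid: GridSpec

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        self.unit_labels = np.asarray(self.unit_labels)
        if self.index.shape != self.unit_labels.shape:
            raise ValueError("index and unit_labels must share a grid")
        if np.nanmin(self.index) < 0 or np.nanmax(self.index) > 1:
            raise ValueError("peat index must lie in [0, 1]")


def block_labels(shape: tuple[int, int], block: int) -> np.ndarray:
    """Rectangular coarse-cell labeling of a fine grid."""
    h, w = shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return (ii // block) * int(np.ceil(w / block)) + (jj // block)


def coarse_areas_from_mask(mask: np.ndarray, unit_labels: np.ndarray,
                           pixel_area: float) -> dict[int, float]:
    """Per-unit peat area implied by a fine mask (used to build test inputs)."""
    mask = np.asarray(mask, dtype=bool)
    out: dict[int, float] = {}
    for lab in np.unique(unit_labels):
        out[int(lab)] = float(mask[unit_labels == lab].sum()) * pixel_area
    return out


def downscale_peat(peat_map: PeatIndexMap) -> np.ndarray:
    """Area-conserving thresholding of the peat index within each coarse unit.

    The target pixel count per unit is the coarse peat area divided by the
    fine pixel area, rounded to the nearest integer (so the conserved area
    is within half a pixel of the coarse one).  Ties on the index are broken
    by ascending flat pixel order, making the selection deterministic.
    """
    grid = peat_map.grid
    pixel_area = grid.pixel_area
    out = np.zeros(grid.shape, dtype=bool)
    flat_index = peat_map.index.ravel()
    flat_labels = peat_map.unit_labels.ravel()
    for lab, area in peat_map.unit_area_m2.items():
        sel = np.nonzero(flat_labels == lab)[0]
        cell_area = sel.size * pixel_area
        if area > cell_area + 0.5 * pixel_area:
            raise ValueError(
                f"coarse peat area {area:.0f} m2 exceeds unit {lab} area "
                f"{cell_area:.0f} m2")
        k = int(round(area / pixel_area))
        k = min(k, sel.size)
        if k <= 0:
            continue
        # sort by (index desc, flat position asc): stable sort on -index
        order = sel[np.argsort(-flat_index[sel], kind="stable")]
        out.ravel()[order[:k]] = True
    return out


def resample_nearest(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upsampling by an integer grid ratio (exact)."""
    return np.repeat(np.repeat(np.asarray(mask), factor, axis=0), factor, axis=1)


@dataclass
class PeatFireResult:
    """Peat/non-peat attribution of burned pixels."""

    peat_fire: dict[int, np.ndarray]
    annual: pd.DataFrame


def classify_peat_fires(burned: dict[int, np.ndarray], peat_mask: np.ndarray,
                        pixel_area: float = 900.0) -> PeatFireResult:
    """Label burned pixels by peat status and build the annual peat-BA series.

    ``burned`` maps year to burned mask.  A burned pixel is a peat fire iff
    it falls on the peat mask; the annual table reports burned area, peat
    burned area (m²) and the peat fraction per year.
    """
    peat_mask = np.asarray(peat_mask, dtype=bool)
    labels: dict[int, np.ndarray] = {}
    rows = []
    for year in sorted(burned):
        mask = np.asarray(burned[year], dtype=bool)
        if mask.shape != peat_mask.shape:
            raise ValueError(f"burned mask of {year} misaligned with peat mask")
        peat_fire = mask & peat_mask
        labels[year] = peat_fire
        n_burn = int(mask.sum())
        n_peat = int(peat_fire.sum())
        rows.append({
            "year": year,
            "burned_area_m2": n_burn * pixel_area,
            "peat_ba_m2": n_peat * pixel_area,
            "peat_fraction": n_peat / n_burn if n_burn else np.nan,
        })
    return PeatFireResult(peat_fire=labels, annual=pd.DataFrame(rows))


@dataclass
class AgreementReport:
    """Agreement of mapped peat-fire labels with reference point labels."""

    n_points: int
    n_on_burned: int
    n_excluded: int
    n_agree: int

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_on_burned if self.n_on_burned else np.nan


def agreement_with_reference(peat_fire: np.ndarray, burned: np.ndarray,
                             points: pd.DataFrame, grid: GridSpec
                             ) -> AgreementReport:
    """Fraction of reference points whose peat label matches the map.

    ``points`` needs columns x, y (meters) and ``is_peat`` (bool).  Points
    falling off the burned mask are excluded but counted.
    """
    peat_fire = np.asarray(peat_fire, dtype=bool)
    burned = np.asarray(burned, dtype=bool)
    px = grid.pixel_size
    rows = np.clip((points["y"].to_numpy() / px).astype(int), 0, grid.height - 1)
    cols = np.clip((points["x"].to_numpy() / px).astype(int), 0, grid.width - 1)
    on_burned = burned[rows, cols]
    labels = peat_fire[rows, cols]
    ref = points["is_peat"].to_numpy(dtype=bool)
    agree = int((labels[on_burned] == ref[on_burned]).sum())
    return AgreementReport(
        n_points=len(points),
        n_on_burned=int(on_burned.sum()),
        n_excluded=int((~on_burned).sum()),
        n_agree=agree,
    )
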