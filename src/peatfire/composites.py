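"""Spectral indices, scene quality filtering and annual min-NBR composites.

A year of dated observations is reduced to a single composite per pixel by
selecting the observation with the lowest Normalized Burn Ratio (NBR), the
strongest spectral fire signal.  Pre-fire-year and post-fire-year composites
are then differenced into a 28-feature stack (9 post + 9 pre + 9 difference
features + a date-difference band) that feeds the burn classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from peatfire.raster import BANDS, GridSpec, NIR, RED, SWIRL, SWIRS, SceneStack

#: The nine per-composite features: six reflectance bands plus three indices.
COMPOSITE_FEATURES = BANDS + ("ndvi", "nbr", "nbr2")

#: The full 28-feature classification stack, in band order.
FEATURE_NAMES = tuple(
    [f"{name}_post" for name in COMPOSITE_FEATURES]
    + [f"{name}_pre" for name in COMPOSITE_FEATURES]
    + [f"{name}_diff" for name in COMPOSITE_FEATURES]
    + ["date_diff"]
)

# Quality-filter thresholds: cloud saturation caps on SWIRL/NIR, the
# Landsat-5 2001-2002 diagonal-stripe NBR2 floor, and the water floor on
# red/NIR reflectance.
SWIRL_CLOUD_MAX = 0.3
NIR_CLOUD_MAX = 0.33
NBR2_STRIPE_MIN = -0.3
WATER_REFLECTANCE_MIN = 0.005

#: Sensor/year combinations subject to the NBR2 stripe filter.
STRIPE_SENSOR = "L5"
STRIPE_YEARS = (2001, 2002)


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a - b) / (a + b), with zero denominators mapped to NaN."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    return np.where(denom == 0, np.nan, out)


def spectral_indices(reflectance: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (NDVI, NBR, NBR2) from reflectance with trailing band axis.

    NDVI = (NIR - red) / (NIR + red);
    NBR = (NIR - long SWIR) / (NIR + long SWIR);
    NBR2 = (short SWIR - long SWIR) / (short SWIR + long SWIR).
    Zero denominators yield NaN, which the quality filter drops.
    """
    refl = np.asarray(reflectance)
    ndvi = _normalized_difference(refl[..., NIR], refl[..., RED])
    nbr = _normalized_difference(refl[..., NIR], refl[..., SWIRL])
    nbr2 = _normalized_difference(refl[..., SWIRS], refl[..., SWIRL])
    return ndvi, nbr, nbr2


def quality_filter(
    reflectance: np.ndarray,
    sensor_tag: str = "L8",
    year: int | None = None,
) -> np.ndarray:
    """Per-observation keep mask for one scene.

    An observation is dropped when the long-SWIR band exceeds 0.3 or the NIR
    band exceeds 0.33 (cloud saturation), when red or NIR reflectance falls
    below 0.005 (open water), or — for Landsat-5 scenes of 2001/2002 — when
    NBR2 drops below -0.3 (diagonal stripe artifact).  NaN indices are also
    dropped.
    """
    refl = np.asarray(reflectance)
    _, _, nbr2 = spectral_indices(refl)
    drop = (
        (refl[..., SWIRL] > SWIRL_CLOUD_MAX)
        | (refl[..., NIR] > NIR_CLOUD_MAX)
        | (refl[..., RED] < WATER_REFLECTANCE_MIN)
        | (refl[..., NIR] < WATER_REFLECTANCE_MIN)
        | ~np.isfinite(nbr2)
    )
    if sensor_tag == STRIPE_SENSOR and (year is None or year in STRIPE_YEARS):
        drop |= nbr2 < NBR2_STRIPE_MIN
    return ~drop


@dataclass
class Composite:
    """Annual min-NBR composite: per-pixel selected observation and its day.

    ``features`` has shape (H, W, 9) in :data:`COMPOSITE_FEATURES` order;
    ``day`` is the day-of-year of the selected observation and ``valid``
    marks pixels with at least one surviving observation.
    """

    features: np.ndarray
    day: np.ndarray
    valid: np.ndarray
    year: int
    grid: GridSpec


def min_nbr_composite(stack: SceneStack) -> Composite:
    """Reduce a scene stack to the per-pixel observation minimizing NBR.

    Observations failing :func:`quality_filter` are excluded.  Ties on NBR
    are broken by the earliest day; pixels with no surviving observation are
    marked invalid.
    """
    order = np.argsort(stack.days, kind="stable")
    refl = stack.reflectance[order]
    days = stack.days[order]
    tags = stack.sensor_tags[order]

    t, h, w, _ = refl.shape
    keep = np.empty((t, h, w), dtype=bool)
    for k in range(t):
        keep[k] = quality_filter(refl[k], sensor_tag=str(tags[k]), year=stack.year)

    ndvi, nbr, nbr2 = spectral_indices(refl)
    nbr_masked = np.where(keep, nbr, np.inf)
    valid = keep.any(axis=0)
    # argmin over scenes sorted by day -> earliest day wins ties.
    sel = np.argmin(nbr_masked, axis=0)

    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    best_refl = refl[sel, ii, jj, :]
    features = np.concatenate(
        [
            best_refl,
            ndvi[sel, ii, jj][..., None],
            nbr[sel, ii, jj][..., None],
            nbr2[sel, ii, jj][..., None],
        ],
        axis=-1,
    ).astype(np.float64)
    day = days[sel].astype(np.int32)
    features[~valid] = np.nan
    day = np.where(valid, day, -1).astype(np.int32)
    return Composite(features=features, day=day, valid=valid, year=stack.year, grid=stack.grid)


@dataclass
class FeatureComposite:
    """The 28-feature per-pixel classification stack for one fire year.

    ``features`` has shape (H, W, 28) ordered as :data:`FEATURE_NAMES`:
    nine post-year features, nine pre-year features, nine differences
    (post - pre) and the date difference in days between the two
    compositing dates.
    """

    features: np.ndarray
    valid: np.ndarray
    post_day: np.ndarray
    year: int
    grid: GridSpec

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def band(self, name: str) -> np.ndarray:
        """Return one named feature plane."""
        return self.features[..., FEATURE_NAMES.index(name)]

    def table(self, rows: np.ndarray, cols: np.ndarray):
        """Feature matrix (n, 28) for the given pixel indices."""
        return self.features[rows, cols, :]


def build_feature_stack(
    pre: Composite, post: Composite, year_gap_days: int = 365
) -> FeatureComposite:
    """Assemble the 28-feature stack from pre- and post-year composites.

    The date difference is ``post_day - pre_day + year_gap_days`` so that a
    pre-composite late in year t-1 and a post-composite early in year t
    yield the true elapsed days across the year boundary.
    """
    if pre.grid.shape != post.grid.shape:
        raise ValueError("pre and post composites must share the same grid")
    valid = pre.valid & post.valid
    diff = post.features - pre.features
    date_diff = (post.day - pre.day + year_gap_days).astype(np.float64)
    features = np.concatenate(
        [post.features, pre.features, diff, date_diff[..., None]], axis=-1
    )
    features[~valid] = np.nan
    return FeatureComposite(
        features=features,
        valid=valid,
        post_day=post.day,
        year=post.year,
        grid=post.grid,
    )
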