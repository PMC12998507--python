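"""Rule-based refinement of the raw burn classification.

Four steps: (1) confirm high-confidence seeds whose burn probability exceeds
the mean probability of the burned training class; (2) grow the burned
region from those seeds through pixels satisfying a relaxed spectral
disjunction, restricted to a 2-km vicinity of seeds and 8-connectivity to
the evolving region; (3) drop connected patches containing fewer than four
seeds; (4) morphological cleanup with 3x3 (90 m) kernels applied literally
as dilation-erosion then erosion-dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from peatfire.classifier import BurnProbabilityMap
from peatfire.composites import FeatureComposite

#: 8-connected (Queen's case) structuring element, used throughout.
QUEEN = np.ones((3, 3), dtype=bool)

#: Growing-region rule thresholds.
GROW_PB_MIN = 0.40
SEED_VICINITY_M = 2000.0
MIN_SEEDS_PER_PATCH = 4


@dataclass
class SeedMask:
    """Confirmed burned seeds and the probability threshold that defined them."""

    seeds: np.ndarray
    seed_threshold: float


def confirm_seeds(pb_map: BurnProbabilityMap, classified: np.ndarray,
                  seed_threshold: float) -> SeedMask:
    """Seeds are classified-burned pixels with P_b strictly above threshold."""
    if not 0.0 < seed_threshold < 1.0:
        raise ValueError("seed_threshold must lie in (0, 1)")
    classified = np.asarray(classified, dtype=bool)
    with np.errstate(invalid="ignore"):
        seeds = classified & pb_map.valid & (pb_map.p_b > seed_threshold)
    return SeedMask(seeds=seeds, seed_threshold=float(seed_threshold))


def growing_rule(stack: FeatureComposite, pb: np.ndarray) -> np.ndarray:
    """The relaxed spectral disjunction a candidate pixel must satisfy.

    ``P_b >= 40%``, or a moderate-confidence clause (NBR2_post <= 0.06,
    NBR2_diff <= 0.005, red_diff >= 0.04, NIR_diff <= -0.003), or a
    high-confidence spectral clause (NBR2_post <= 0, NBR2_diff <= 0.01,
    red_post <= 0.03).
    """
    nbr2_post = stack.band("nbr2_post")
    nbr2_diff = stack.band("nbr2_diff")
    red_diff = stack.band("red_diff")
    nir_diff = stack.band("nir_diff")
    red_post = stack.band("red_post")
    with np.errstate(invalid="ignore"):
        clause1 = pb >= GROW_PB_MIN
        clause2 = ((nbr2_post <= 0.06) & (nbr2_diff <= 0.005)
                   & (red_diff >= 0.04) & (nir_diff <= -0.003))
        clause3 = (nbr2_post <= 0.0) & (nbr2_diff <= 0.01) & (red_post <= 0.03)
    out = (np.nan_to_num(clause1 | clause2 | clause3)).astype(bool)
    return out & stack.valid


def grow_region(seed_mask: SeedMask, stack: FeatureComposite,
                pb_map: BurnProbabilityMap,
                vicinity_m: float = SEED_VICINITY_M) -> np.ndarray:
    """Grow the burned region from confirmed seeds to a fixed point.

    A pixel joins the region iff it satisfies :func:`growing_rule`, lies
    within ``vicinity_m`` of the nearest seed, and is 8-connected to the
    current region.  Growth is run to convergence, so the result is the
    order-independent connected closure; it always contains the seeds.
    """
    seeds = seed_mask.seeds
    if not seeds.any():
        return seeds.copy()
    px = stack.grid.pixel_size
    dist = ndimage.distance_transform_edt(~seeds, sampling=px)
    candidates = growing_rule(stack, pb_map.p_b) & (dist <= vicinity_m)
    grown = ndimage.binary_dilation(
        seeds, structure=QUEEN, iterations=0, mask=candidates | seeds)
    return grown


def filter_patches_by_seeds(burned: np.ndarray, seed_mask: SeedMask,
                            min_seeds: int = MIN_SEEDS_PER_PATCH) -> np.ndarray:
    """Remove 8-connected patches containing fewer than ``min_seeds`` seeds."""
    burned = np.asarray(burned, dtype=bool)
    labels, n = ndimage.label(burned, structure=QUEEN)
    if n == 0:
        return burned.copy()
    seed_counts = ndimage.sum_labels(
        seed_mask.seeds.astype(np.int64), labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = seed_counts >= min_seeds
    return keep[labels]


def morphological_cleanup(mask: np.ndarray) -> np.ndarray:
    """Dilation-erosion then erosion-dilation with a 3x3 (90 m) kernel.

    The operator order follows the mapping rule literally — "opening"
    defined as dilation-then-erosion and "closing" as erosion-then-dilation,
    applied in that order — i.e. a standard morphological closing followed
    by a standard opening.  The first pair fills single-pixel holes, the
    second removes isolated pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    step1 = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, structure=QUEEN), structure=QUEEN)
    step2 = ndimage.binary_dilation(
        ndimage.binary_erosion(step1, structure=QUEEN), structure=QUEEN)
    return step2


def refine(pb_map: BurnProbabilityMap, stack: FeatureComposite,
           classified: np.ndarray | None = None,
           seed_threshold: float | None = None,
           burned_train_mean_pb: float | None = None) -> tuple[np.ndarray, SeedMask]:
    """Full post-processing chain from a probability map to a refined mask."""
    if classified is None:
        with np.errstate(invalid="ignore"):
            classified = pb_map.valid & (np.nan_to_num(pb_map.p_b) >= 0.5)
    if seed_threshold is None:
        if burned_train_mean_pb is None:
            raise ValueError("need seed_threshold or burned_train_mean_pb")
        seed_threshold = burned_train_mean_pb
    seed_mask = confirm_seeds(pb_map, classified, seed_threshold)
    grown = grow_region(seed_mask, stack, pb_map)
    filtered = filter_patches_by_seeds(grown, seed_mask)
    cleaned = morphological_cleanup(filtered)
    return cleaned, seed_mask
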