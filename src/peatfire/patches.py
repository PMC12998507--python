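"""Spatiotemporal fire-patch clustering, tile merging and overwintering flags.

Dated burned pixels are aggregated into fire events by flood-fill: two
pixels belong to the same patch when linked by a chain of neighbor pairs —
8-connectivity extended to any pixels within a ~150-m bridging buffer (to
jump rivers and other narrow barriers) — whose burn days differ by at most
a cutoff (16 days by default, optimal within the 12-24 day trial range for
slow-spreading, cloud-obscured boreal fires).  Patches of a year are
flagged as overwintering when they ignite before July 1 within 1 km of a
previous-season patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


JULY_1 = 182  # day-of-year of July 1 in non-leap years (183 in leap years)
OVERWINTER_MAX_DIST_M = 1000.0
LARGE_FIRE_HA = 1000.0


@dataclass
class ClusterConfig:
    """Flood-fill clustering parameters."""

    cutoff_days: float = 16.0
    bridge_buffer_m: float = 150.0
    tile_size: int = 64  # pixels per square tile for windowed processing

    def __post_init__(self) -> None:
        if not 12.0 <= self.cutoff_days <= 24.0:
            raise ValueError("cutoff_days must lie in the 12-24 day trial range")
        if self.bridge_buffer_m < 0:
            raise ValueError("bridge_buffer_m must be >= 0")


@dataclass
class FirePatch:
    """One clustered fire event."""

    patch_id: int
    year: int
    rows: np.ndarray
    cols: np.ndarray
    days: np.ndarray
    pixel_size: float = 30.0
    n_seeds: int = 0
    peat_fraction: float = 0.0
    overwintering: bool = False
    origin_patch_id: int | None = None
    origin_peat_in_corridor: bool | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    @property
    def start_day(self) -> float:
        return float(self.days.min())

    @property
    def end_day(self) -> float:
        return float(self.days.max())

    @property
    def duration(self) -> float:
        return self.end_day - self.start_day

    @property
    def size_ha(self) -> float:
        """Patch area in hectares (pixel count x 0.09 ha at 30-m pixels)."""
        return self.n_pixels * self.pixel_size**2 / 1e4

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid in meters."""
        return (
            float((self.cols.mean() + 0.5) * self.pixel_size),
            float((self.rows.mean() + 0.5) * self.pixel_size),
        )

    def key(self) -> tuple:
        """Canonical identity of the pixel set, used for deduplication."""
        flat = np.sort(self.rows.astype(np.int64) * 10_000_000 + self.cols)
        return (self.year, self.n_pixels, int(flat[0]), int(flat[-1]),
                int(flat.sum() % (2**62)))


class UndatedPixelError(ValueError):
    """Raised when burned pixels lack a burn day."""


def _link_radius(cfg: ClusterConfig, pixel_size: float) -> float:
    """Neighbor radius in meters: 8-connectivity extended by the bridge buffer."""
    return max(cfg.bridge_buffer_m, pixel_size * np.sqrt(2) * 1.0001)


def cluster_patches(day_raster: np.ndarray, cfg: ClusterConfig | None = None,
                    year: int = 0, pixel_size: float = 30.0,
                    burned: np.ndarray | None = None) -> list[FirePatch]:
    """Flood-fill clustering of a dated burn raster into fire patches.

    ``day_raster`` holds the burn day-of-year per burned pixel and NaN
    elsewhere; alternatively pass an explicit ``burned`` mask (undated
    burned pixels then raise :class:`UndatedPixelError` listing offenders).
    """
    cfg = cfg or ClusterConfig()
    day_raster = np.asarray(day_raster, dtype=float)
    if burned is None:
        burned = np.isfinite(day_raster)
    else:
        burned = np.asarray(burned, dtype=bool)
        bad = burned & ~np.isfinite(day_raster)
        if bad.any():
            rr, cc = np.nonzero(bad)
            listing = ", ".join(f"({r},{c})" for r, c in zip(rr[:10], cc[:10]))
            raise UndatedPixelError(
                f"{rr.size} burned pixels lack a burn day (first: {listing})")
    rr, cc = np.nonzero(burned)
    n = rr.size
    if n == 0:
        return []
    days = day_raster[rr, cc]
    coords = np.column_stack([cc + 0.5, rr + 0.5]) * pixel_size
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=_link_radius(cfg, pixel_size), output_type="ndarray")
    if pairs.size:
        ok = np.abs(days[pairs[:, 0]] - days[pairs[:, 1]]) <= cfg.cutoff_days
        pairs = pairs[ok]
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    patches = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        patches.append(FirePatch(
            patch_id=comp, year=year, rows=rr[idx], cols=cc[idx],
            days=days[idx], pixel_size=pixel_size))
    # deterministic ordering: by first (row, col) pixel
    patches.sort(key=lambda p: (int(p.rows.min()),
                                int(p.cols[p.rows.argmin()])))
    for i, p in enumerate(patches):
        p.patch_id = i
    return patches


def merge_tiles(day_raster: np.ndarray, cfg: ClusterConfig | None = None,
                year: int = 0, pixel_size: float = 30.0) -> list[FirePatch]:
    """Windowed clustering equivalent to whole-raster clustering.

    Each tile is clustered within a rolling 3x3-tile window centered on it;
    patches touching the center tile are kept and duplicates (the same
    pixel set seen from neighboring windows) removed.  For patches smaller
    than one tile span the result equals :func:`cluster_patches` on the
    full raster.
    """
    cfg = cfg or ClusterConfig()
    day_raster = np.asarray(day_raster, dtype=float)
    h, w = day_raster.shape
    ts = cfg.tile_size
    n_ti = int(np.ceil(h / ts))
    n_tj = int(np.ceil(w / ts))
    seen: dict[tuple, FirePatch] = {}
    for ti in range(n_ti):
        for tj in range(n_tj):
            i0, i1 = max(0, (ti - 1) * ts), min(h, (ti + 2) * ts)
            j0, j1 = max(0, (tj - 1) * ts), min(w, (tj + 2) * ts)
            sub = day_raster[i0:i1, j0:j1]
            if not np.isfinite(sub).any():
                continue
            for p in cluster_patches(sub, cfg, year=year, pixel_size=pixel_size):
                rows, cols = p.rows + i0, p.cols + j0
                # keep only patches intersecting the center tile
                in_center = ((rows // ts == ti) & (cols // ts == tj)).any()
                if not in_center:
                    continue
                patch = FirePatch(patch_id=0, year=year, rows=rows, cols=cols,
                                  days=p.days, pixel_size=pixel_size)
                seen.setdefault(patch.key(), patch)
    patches = sorted(seen.values(),
                     key=lambda p: (int(p.rows.min()),
                                    int(p.cols[p.rows.argmin()])))
    for i, p in enumerate(patches):
        p.patch_id = i
    return patches


def flag_overwintering(patches: list[FirePatch],
                       previous: list[FirePatch],
                       peat_mask: np.ndarray | None = None,
                       max_dist_m: float = OVERWINTER_MAX_DIST_M,
                       july1: int = JULY_1) -> list[FirePatch]:
    """Flag patches reigniting before July 1 within 1 km of last season's fires.

    Distance is edge-to-edge between pixel sets (overwintering emerges at
    fire perimeters).  The linkage records the nearest qualifying origin
    patch and whether peatland occurs in the 1-km corridor between the two
    patches (pixels within ``max_dist_m`` of both).
    """
    if not previous:
        for p in patches:
            p.overwintering = False
        return patches
    prev_coords = []
    prev_ids = []
    for q in previous:
        prev_coords.append(np.column_stack([q.cols + 0.5, q.rows + 0.5])
                           * q.pixel_size)
        prev_ids.append(np.full(q.n_pixels, q.patch_id))
    prev_coords = np.vstack(prev_coords)
    prev_ids = np.concatenate(prev_ids)
    tree = cKDTree(prev_coords)
    prev_by_id = {q.patch_id: q for q in previous}
    for p in patches:
        p.overwintering = False
        p.origin_patch_id = None
        p.origin_peat_in_corridor = None
        if p.start_day >= july1:
            continue
        coords = np.column_stack([p.cols + 0.5, p.rows + 0.5]) * p.pixel_size
        dist, idx = tree.query(coords)
        k = int(dist.argmin())
        if dist[k] > max_dist_m:
            continue
        p.overwintering = True
        origin = prev_by_id[int(prev_ids[idx[k]])]
        p.origin_patch_id = origin.patch_id
        if peat_mask is not None:
            p.origin_peat_in_corridor = _peat_in_corridor(
                p, origin, peat_mask, max_dist_m)
    return patches


def _peat_in_corridor(p: FirePatch, origin: FirePatch, peat_mask: np.ndarray,
                      max_dist_m: float) -> bool:
    """Any peat pixel within ``max_dist_m`` of both patches' pixel sets."""
    peat_mask = np.asarray(peat_mask, dtype=bool)
    pr, pc = np.nonzero(peat_mask)
    if pr.size == 0:
        return False
    peat_xy = np.column_stack([pc + 0.5, pr + 0.5]) * p.pixel_size
    d_new = cKDTree(np.column_stack([p.cols + 0.5, p.rows + 0.5])
                    * p.pixel_size).query(peat_xy)[0]
    d_old = cKDTree(np.column_stack([origin.cols + 0.5, origin.rows + 0.5])
                    * origin.pixel_size).query(peat_xy)[0]
    return bool(((d_new <= max_dist_m) & (d_old <= max_dist_m)).any())


def attach_peat_fraction(patches: list[FirePatch],
                         peat_mask: np.ndarray) -> list[FirePatch]:
    """Set each patch's fraction of pixels on mapped peatland."""
    peat_mask = np.asarray(peat_mask, dtype=bool)
    for p in patches:
        p.peat_fraction = float(peat_mask[p.rows, p.cols].mean()) if p.n_pixels else 0.0
    return patches


def attach_seed_counts(patches: list[FirePatch],
                       seeds: np.ndarray) -> list[FirePatch]:
    """Set each patch's confirmed-seed count."""
    seeds = np.asarray(seeds, dtype=bool)
    for p in patches:
        p.n_seeds = int(seeds[p.rows, p.cols].sum())
    return patches


def patch_summaries(patches: list[FirePatch],
                    large_fire_ha: float = LARGE_FIRE_HA) -> pd.DataFrame:
    """Attribute table of patches with size classes and large-fire flags."""
    columns = ["patch_id", "year", "n_pixels", "size_ha", "start_day",
               "end_day", "duration", "n_seeds", "peat_fraction",
               "overwintering", "size_class", "large_fire",
               "centroid_x", "centroid_y"]
    rows = []
    bins = [0.0, 10.0, 100.0, large_fire_ha, np.inf]
    names = ["<10 ha", "10-100 ha", f"100-{large_fire_ha:.0f} ha",
             f">{large_fire_ha:.0f} ha"]
    for p in patches:
        size = p.size_ha
        cls = names[int(np.searchsorted(bins, size, side="right")) - 1]
        cx, cy = p.centroid
        rows.append({
            "patch_id": p.patch_id, "year": p.year, "n_pixels": p.n_pixels,
            "size_ha": size, "start_day": p.start_day, "end_day": p.end_day,
            "duration": p.duration, "n_seeds": p.n_seeds,
            "peat_fraction": p.peat_fraction, "overwintering": p.overwintering,
            "size_class": cls, "large_fire": size > large_fire_ha,
            "centroid_x": cx, "centroid_y": cy,
        })
    return pd.DataFrame(rows, columns=columns)
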