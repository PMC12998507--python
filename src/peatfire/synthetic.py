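"""Seeded synthetic fire landscapes with known ground truth.

The generator emulates the inputs of a boreal burned-area/peat-fire analysis
at desk scale: multi-date six-band reflectance stacks over a planar 30-m
grid, elliptical fire scars that expand over days (giving each burned pixel
an ignition day), active-fire point detections sampled along the fire front,
a smooth peatland-plausibility field with an area-consistent coarse map,
field combustion plots with a depth-to-belowground-combustion linear link
calibrated to a Pearson correlation of 0.75, and an annual climate series
with an exponential climate-to-burned-area link.

Reflectance uses piecewise-constant archetypes (vegetated / burned / water /
cloud) plus Gaussian noise: classifiers downstream only require spectral
separability and controlled confusion, not radiative-transfer realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from peatfire.raster import GridSpec, SceneStack

# ---------------------------------------------------------------------------
# Spectral archetypes (blue, green, red, nir, swirs, swirl).
# Vegetated NBR = +0.50, burned NBR = -0.52: burning drops NIR and raises the
# long SWIR band.  Cloud NIR/SWIRL sit above the 0.33/0.30 quality caps;
# water red/NIR sit below the 0.005 floor.
VEGETATED = np.array([0.03, 0.05, 0.04, 0.30, 0.15, 0.10])
BURNED = np.array([0.04, 0.05, 0.09, 0.08, 0.20, 0.25])
CLOUD = np.array([0.35, 0.38, 0.40, 0.50, 0.35, 0.45])

#: March-November compositing window (day of year, inclusive).
SEASON_START, SEASON_END = 60, 334

#: Field-plot region labels and their sample proportions (285:568:41).
REGIONS = ("Alaska", "Canada", "Siberia")
REGION_COUNTS_894 = (285, 568, 41)

#: Predictors informative for burn depth in the synthetic link.
INFORMATIVE_PREDICTORS = ("soil_carbon_density", "water_deficit", "tree_cover")

_NUISANCE_PREDICTORS = (
    "dc", "dmc", "pdsi", "soil_moisture", "tmin", "tmax", "precip_summer",
    "vpd", "elevation", "slope", "aspect", "twi", "bulk_density",
    "clay_fraction", "sand_fraction", "soil_ph", "ndvi_prefire",
    "nbr_prefire", "dnbr", "fire_duration", "fire_size", "doy_burn",
    "latitude_norm", "longitude_norm", "snow_free_days", "permafrost_prob",
    "peat_depth", "org_layer_depth", "moss_cover", "shrub_cover",
    "larch_fraction", "stand_age", "rh_summer", "wind_speed", "gdd",
    "thaw_depth", "albedo", "swe_spring", "drainage_density",
)

#: 42 candidate predictors for the depth / belowground models.
DEPTH_PREDICTORS = INFORMATIVE_PREDICTORS + _NUISANCE_PREDICTORS
#: 43 candidate predictors for the aboveground model (adds biomass).
ABOVE_PREDICTORS = DEPTH_PREDICTORS + ("aboveground_biomass",)

assert len(DEPTH_PREDICTORS) == 42 and len(ABOVE_PREDICTORS) == 43

# Depth link: depth(cm) = 2 + 0.25*soilC + 1.8*wd_z + 0.05*tree_cover + eps.
# With the plot predictor spreads below, the noise level leaves roughly half
# of the depth variance explainable, mirroring realistic field predictability.
DEPTH_COEF = {"intercept": 2.0, "soil_carbon_density": 0.25,
              "water_deficit": 1.8, "tree_cover": 0.05}
DEPTH_NOISE_SD = 3.2

# Belowground combustion (g C m-2) = 500 + 250*depth + site + eps, with the
# site/noise spread calibrated so r(depth, belowground) = 0.75.
BELOW_INTERCEPT = 500.0
BELOW_SLOPE = 250.0
BELOW_SITE_SD = 400.0
BELOW_NOISE_SD = 908.0

# Aboveground combustion (g C m-2) = 50 + 0.25*biomass + 0.5*tree_cover + eps.
ABOVE_INTERCEPT = 50.0
ABOVE_BIOMASS_SLOPE = 0.25
ABOVE_TREE_SLOPE = 0.5
ABOVE_NOISE_SD = 140.0

# Exponential climate-fire link: peat BA (Mha) = exp(a + b*z) * lognormal.
# The noise level emulates the Arctic-strength climate sensitivity (log-scale
# R² ~ 0.86): at n = 23 years this is the regime in which the slope is
# recoverable to within ±20% with high probability.
CLIMATE_A = 0.0
CLIMATE_B = 0.5
CLIMATE_LOG_NOISE_SD = 0.2
BASELINE_YEARS = (1958, 2023)
FIRE_YEARS = (2001, 2023)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Configuration of one synthetic landscape run.

    Dimensions are pixels on a planar grid of ``pixel_size``-meter squares;
    ``years`` counts fire years (one burn-free spin-up year is always added
    in front so the first fire year has a pre-composite).
    """

    grid_height: int = 128
    grid_width: int = 128
    pixel_size: float = 30.0
    years: int = 3
    start_year: int = 2015
    cloud_fraction: float = 0.15
    n_scars_per_year: int = 3
    scar_size_range: tuple[int, int] = (6, 14)
    water_fraction: float = 0.05
    peat_fraction: float = 0.30
    n_field_plots: int = 894
    rng_seed: int = 0
    scene_interval_days: int = 16
    noise_sd: float = 0.008
    n_overwinter_per_year: int = 1
    n_late_scars_per_year: int = 1
    af_footprint_m: float = 375.0
    af_interval_days: int = 3
    af_per_day: int = 2
    depth_noise_sd: float = DEPTH_NOISE_SD
    below_noise_sd: float = BELOW_NOISE_SD
    below_site_sd: float = BELOW_SITE_SD
    above_noise_sd: float = ABOVE_NOISE_SD
    climate_a: float = CLIMATE_A
    climate_b: float = CLIMATE_B
    climate_log_noise_sd: float = CLIMATE_LOG_NOISE_SD

    def __post_init__(self) -> None:
        for name in ("cloud_fraction", "water_fraction", "peat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.grid_height < 32 or self.grid_width < 32:
            raise ConfigurationError("grid dimensions must be >= 32 pixels")
        if self.years < 1:
            raise ConfigurationError("years must be >= 1")
        lo, hi = self.scar_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("scar_size_range must satisfy 0 < lo <= hi")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_height, self.grid_width, self.pixel_size)

    @property
    def fire_years(self) -> list[int]:
        return [self.start_year + i for i in range(self.years)]


@dataclass
class GroundTruth:
    """Known truth of one synthetic run, keyed by fire year where per-year."""

    grid: GridSpec
    scar_mask: dict[int, np.ndarray]
    ignition_day: dict[int, np.ndarray]
    peat_mask: np.ndarray
    peat_index: np.ndarray
    water_mask: np.ndarray
    water_cover: np.ndarray
    af_records: pd.DataFrame
    scar_table: pd.DataFrame
    base_fields: dict[str, np.ndarray]
    water_deficit_z: dict[int, float]
    plot_truth: pd.DataFrame | None = None
    climate_truth: dict | None = None
    sem_truth: dict | None = None

    def burned_through(self, year: int) -> np.ndarray:
        """Union of scar masks for all fire years up to and including ``year``."""
        out = np.zeros(self.grid.shape, dtype=bool)
        for y, mask in self.scar_mask.items():
            if y <= year:
                out |= mask
        return out


# ---------------------------------------------------------------------------
# helpers


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 8.0) -> np.ndarray:
    """Zero-mean, unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _threshold_topk(field: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask selecting the top ``fraction`` of pixels by field value."""
    k = int(round(fraction * field.size))
    mask = np.zeros(field.size, dtype=bool)
    if k > 0:
        order = np.argsort(field, axis=None, kind="stable")
        mask[order[-k:]] = True
    return mask.reshape(field.shape)


@dataclass
class _Scar:
    year: int
    scar_id: int
    kind: str  # normal | overwinter | late
    row: float
    col: float
    ax_r: float
    ax_c: float
    angle: float
    start_day: float
    duration: float

    def rho(self, shape) -> np.ndarray:
        """Normalized elliptical radius of every pixel (<= 1 inside)."""
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        dr = rr - self.row
        dc = cc - self.col
        u = dr * np.cos(self.angle) + dc * np.sin(self.angle)
        v = -dr * np.sin(self.angle) + dc * np.cos(self.angle)
        return np.sqrt((u / self.ax_r) ** 2 + (v / self.ax_c) ** 2)

    @property
    def radius(self) -> float:
        return max(self.ax_r, self.ax_c)


def _place_scars(cfg: SimConfig, rng: np.random.Generator,
                 water: np.ndarray) -> list[_Scar]:
    """Lay out scar ellipses for all fire years with per-pixel burn days.

    Each year gets ``n_scars_per_year`` main-season scars; from the second
    fire year on, the first ones are overwintering children placed within
    1 km of a previous-year scar and igniting before July 1.  Optionally a
    late-season scar igniting after the last observation of the year is
    planted (except in the final year) to exercise the year-relocation rule.
    """
    h, w = cfg.grid_height, cfg.grid_width
    lo, hi = cfg.scar_size_range
    scars: list[_Scar] = []
    next_id = 0

    def sample_axes():
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.55, 1.0)
        return a, b

    def ok_position(row, col, radius, year) -> bool:
        margin = radius + 2
        if not (margin <= row < h - margin and margin <= col < w - margin):
            return False
        if water[int(row), int(col)]:
            return False
        for s in scars:
            # no overlap within a year; keep late scars isolated so the
            # relocation test is well posed
            gap = 3 if s.year == year else (8 if s.kind == "late" else -radius)
            if s.year in (year, year - 1) or s.kind == "late":
                d = np.hypot(s.row - row, s.col - col)
                if d < s.radius + radius + max(gap, 0) and (
                    s.year == year or s.kind == "late"
                ):
                    return False
        return True

    for yi, year in enumerate(cfg.fire_years):
        prev = [s for s in scars if s.year == year - 1 and s.kind != "late"]
        n_over = cfg.n_overwinter_per_year if (yi > 0 and prev) else 0
        for k in range(cfg.n_scars_per_year):
            ax_r, ax_c = sample_axes()
            radius = max(ax_r, ax_c)
            placed = False
            for _ in range(300):
                if k < n_over:
                    parent = prev[int(rng.integers(len(prev)))]
                    theta = rng.uniform(0, 2 * np.pi)
                    # center distance = sum of radii + 90-600 m edge gap
                    d = parent.radius + radius + rng.uniform(3, 20)
                    row = parent.row + d * np.sin(theta)
                    col = parent.col + d * np.cos(theta)
                else:
                    row = rng.uniform(0, h)
                    col = rng.uniform(0, w)
                if ok_position(row, col, radius, year):
                    placed = True
                    break
            if not placed:
                continue
            if k < n_over:
                start = rng.uniform(150, 175)  # before July 1
                kind = "overwinter"
            else:
                start = rng.uniform(190, 250)  # main season
                kind = "normal"
            scars.append(
                _Scar(year, next_id, kind, row, col, ax_r, ax_c,
                      rng.uniform(0, np.pi), start, rng.uniform(15, 35))
            )
            next_id += 1
        if yi < cfg.years - 1:
            for _ in range(cfg.n_late_scars_per_year):
                ax_r, ax_c = sample_axes()
                radius = max(ax_r, ax_c)
                for _ in range(300):
                    row = rng.uniform(0, h)
                    col = rng.uniform(0, w)
                    if ok_position(row, col, radius, year):
                        # ignites after the season's last usable scene
                        scars.append(
                            _Scar(year, next_id, "late", row, col, ax_r, ax_c,
                                  rng.uniform(0, np.pi), 333.0, 1.0)
                        )
                        next_id += 1
                        break
    return scars


def _sample_active_fires(cfg: SimConfig, rng: np.random.Generator,
                         scars: list[_Scar], ignition: dict[int, np.ndarray],
                         scar_ids: dict[int, np.ndarray]) -> pd.DataFrame:
    """Active-fire points sampled along each scar's expanding front.

    Footprints are a per-record attribute capped at the nominal sensor
    footprint but shrunk to the locally burned extent near scar edges, so a
    record's painted rectangle stays inside the truth scar (detections here
    report fire that fills the footprint; real edge-overhanging detections
    are a known commission source the pipeline tolerates, not a property
    the truth should encode).
    """
    from scipy.ndimage import distance_transform_edt

    px = cfg.pixel_size
    rows_out: list[dict] = []
    for s in scars:
        ign = ignition[s.year]
        ids = scar_ids[s.year]
        mask = ids == s.scar_id
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            continue
        # Euclidean depth inside the scar; a centered square of half-extent h
        # is contained when h*sqrt(2) does not exceed the local depth.
        depth_m = distance_transform_edt(mask, sampling=px)[rr, cc]
        half = np.minimum(cfg.af_footprint_m / 2.0,
                          depth_m / np.sqrt(2.0) - 0.1 * px)
        half = np.maximum(half, 0.45 * px)
        days = ign[rr, cc]
        for d in np.arange(np.floor(s.start_day), s.start_day + s.duration + 1,
                           cfg.af_interval_days):
            band = np.abs(days - d) <= max(cfg.af_interval_days / 2, 1.0)
            idx = np.nonzero(band)[0]
            if idx.size == 0:
                continue
            take = idx if idx.size <= cfg.af_per_day else rng.choice(
                idx, size=cfg.af_per_day, replace=False)
            for i in take:
                rows_out.append({
                    "x": (cc[i] + 0.5) * px + rng.uniform(-10, 10),
                    "y": (rr[i] + 0.5) * px + rng.uniform(-10, 10),
                    "day": int(round(days[i])),
                    "year": s.year,
                    "along_track_m": 2.0 * half[i],
                    "cross_track_m": 2.0 * half[i],
                    "scar_id": s.scar_id,
                })
    cols = ["x", "y", "day", "year", "along_track_m", "cross_track_m", "scar_id"]
    return pd.DataFrame(rows_out, columns=cols)


# ---------------------------------------------------------------------------
# main operations


def simulate_scenes(cfg: SimConfig) -> tuple[dict[int, SceneStack], GroundTruth]:
    """Generate per-year scene stacks and the matching ground truth.

    Returns stacks for the spin-up year and every fire year.  Burned pixels
    switch to the burned archetype from their ignition day onward and stay
    burned in later years (so only the ignition year shows a spectral
    difference).  Cloud blobs are painted over land only; water pixels keep
    red/NIR below the 0.005 quality floor in every scene.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    grid = cfg.grid
    h, w = grid.shape

    water = _threshold_topk(_smooth_field(rng, (h, w), 6.0), cfg.water_fraction)
    peat_field = _smooth_field(rng, (h, w), 10.0)
    peat_mask = _threshold_topk(peat_field, cfg.peat_fraction)
    ranks = np.argsort(np.argsort(peat_field, axis=None))
    peat_index = (ranks / (peat_field.size - 1)).reshape(h, w)

    water_cover = np.where(water, 1.0, rng.uniform(0.0, 0.2, (h, w)))

    scars = _place_scars(cfg, rng, water)
    ignition: dict[int, np.ndarray] = {}
    scar_ids: dict[int, np.ndarray] = {}
    burned_before = np.zeros((h, w), dtype=bool)
    for year in cfg.fire_years:
        ign = np.full((h, w), np.nan)
        ids = np.full((h, w), -1, dtype=np.int32)
        for s in [s for s in scars if s.year == year]:
            rho = s.rho((h, w))
            mask = (rho <= 1.0) & ~water & ~burned_before & (ids < 0)
            ign[mask] = s.start_day + rho[mask] * s.duration
            ids[mask] = s.scar_id
        ignition[year] = ign
        scar_ids[year] = ids
        burned_before |= ids >= 0

    scar_mask = {y: scar_ids[y] >= 0 for y in cfg.fire_years}

    # truth overwintering flags follow the definitional rule applied to truth
    # geometry: ignition before July 1 within 1 km of a previous-year scar
    table_rows = []
    px = cfg.pixel_size
    for s in scars:
        rr, cc = np.nonzero(scar_ids[s.year] == s.scar_id)
        over = False
        if rr.size and s.start_day < 182 and s.year - 1 in scar_mask:
            pr, pc = np.nonzero(scar_mask[s.year - 1])
            if pr.size:
                d2 = ((rr[:, None] - pr[None, :]) ** 2
                      + (cc[:, None] - pc[None, :]) ** 2)
                over = bool(np.sqrt(d2.min()) * px <= 1000.0)
        table_rows.append({
            "year": s.year, "scar_id": s.scar_id, "kind": s.kind,
            "row": s.row, "col": s.col, "start_day": s.start_day,
            "duration": s.duration, "n_pixels": int(rr.size),
            "overwintering_truth": over,
        })
    scar_table = pd.DataFrame(table_rows)

    af_records = _sample_active_fires(cfg, rng, scars, ignition, scar_ids)

    base_fields = {
        "soil_carbon_density": 30.0 + 8.0 * _smooth_field(rng, (h, w), 10.0),
        "tree_cover": np.clip(50.0 + 23.0 * _smooth_field(rng, (h, w), 12.0), 0, 100),
        "aboveground_biomass": np.clip(
            1500.0 + 500.0 * _smooth_field(rng, (h, w), 12.0), 0, None),
    }
    for name in _NUISANCE_PREDICTORS:
        base_fields[name] = _smooth_field(rng, (h, w), 9.0)
    wd_z = {y: float(rng.normal(0.0, 1.0)) for y in cfg.fire_years}

    # render scenes
    scene_days = np.arange(SEASON_START, SEASON_END + 1, cfg.scene_interval_days)
    stacks: dict[int, SceneStack] = {}
    all_years = [cfg.start_year - 1] + cfg.fire_years
    cum_prev = {all_years[0]: np.zeros((h, w), dtype=bool)}
    for i, y in enumerate(cfg.fire_years):
        cum_prev[y] = cum_prev[all_years[i]] | scar_mask.get(all_years[i], np.zeros((h, w), bool))

    for year in all_years:
        refl = np.empty((len(scene_days), h, w, 6), dtype=np.float32)
        for k, day in enumerate(scene_days):
            scene = np.broadcast_to(VEGETATED, (h, w, 6)).copy()
            burned_now = cum_prev[year].copy()
            if year in ignition:
                burned_now |= np.nan_to_num(ignition[year], nan=np.inf) <= day
            scene[burned_now] = BURNED
            if cfg.noise_sd > 0:
                scene += rng.normal(0.0, cfg.noise_sd, scene.shape)
            if cfg.cloud_fraction > 0:
                cloud = _cloud_mask(rng, (h, w), cfg.cloud_fraction, water)
                scene[cloud] = CLOUD + (
                    rng.normal(0.0, cfg.noise_sd, (int(cloud.sum()), 6))
                    if cfg.noise_sd > 0 else 0.0)
            scene[water, :] = 0.02
            nw = int(water.sum())
            scene[water, 2] = rng.uniform(0.001, 0.0045, nw)
            scene[water, 3] = rng.uniform(0.001, 0.0045, nw)
            refl[k] = np.clip(scene, 0.0001, 1.2)
        tag = "L5" if year in (2001, 2002) else "L8"
        stacks[year] = SceneStack(
            reflectance=refl, days=scene_days, year=year,
            sensor_tags=np.array([tag] * len(scene_days)), grid=grid)

    truth = GroundTruth(
        grid=grid, scar_mask=scar_mask, ignition_day=ignition,
        peat_mask=peat_mask, peat_index=peat_index, water_mask=water,
        water_cover=water_cover, af_records=af_records, scar_table=scar_table,
        base_fields=base_fields, water_deficit_z=wd_z)
    return stacks, truth


def _cloud_mask(rng: np.random.Generator, shape, fraction: float,
                water: np.ndarray) -> np.ndarray:
    """Random cloud disks over land approximating the target cover fraction."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    target = fraction * (h * w)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for _ in range(200):
        if mask.sum() >= target:
            break
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(5, 14)
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return mask & ~water


def region_counts(n: int) -> dict[str, int]:
    """Largest-remainder allocation of n plots to the 285:568:41 proportions."""
    props = np.array(REGION_COUNTS_894, dtype=float) / sum(REGION_COUNTS_894)
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return dict(zip(REGIONS, counts.tolist()))


def simulate_field_plots(cfg: SimConfig, truth: GroundTruth | None = None,
                         n: int | None = None) -> pd.DataFrame:
    """Field combustion plots with a calibrated depth-combustion link.

    Burn depth follows a linear function of three informative predictors
    (soil carbon density, water-deficit z-score, tree cover) plus noise;
    belowground carbon combustion is ``500 + 250*depth`` plus a per-region
    site term and noise, calibrated so the sample Pearson correlation
    between depth and belowground combustion is 0.75.  Region labels follow
    the 285:568:41 Alaska:Canada:Siberia proportions.  The noise-free truth
    per plot is stored in ``truth.plot_truth`` when ``truth`` is given.
    """
    n = int(n if n is not None else cfg.n_field_plots)
    if n < 50:
        raise ConfigurationError("n_field_plots must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 101]))

    counts = region_counts(n)
    region = np.concatenate([[r] * counts[r] for r in REGIONS])
    site_offsets = {r: rng.normal(0.0, cfg.below_site_sd) for r in REGIONS}

    df = pd.DataFrame({"region": region})
    df["soil_carbon_density"] = rng.normal(30.0, 8.0, n)
    df["water_deficit"] = rng.normal(0.0, 1.2, n)
    df["tree_cover"] = rng.uniform(10.0, 90.0, n)
    for name in _NUISANCE_PREDICTORS:
        df[name] = rng.standard_normal(n)
    df["aboveground_biomass"] = np.clip(rng.normal(1500.0, 500.0, n), 0, None)

    depth_signal = (DEPTH_COEF["intercept"]
                    + DEPTH_COEF["soil_carbon_density"] * df["soil_carbon_density"]
                    + DEPTH_COEF["water_deficit"] * df["water_deficit"]
                    + DEPTH_COEF["tree_cover"] * df["tree_cover"]).to_numpy()
    depth = np.clip(depth_signal + rng.normal(0.0, cfg.depth_noise_sd, n), 0.5, None)
    site = np.array([site_offsets[r] for r in region])
    below_signal = BELOW_INTERCEPT + BELOW_SLOPE * depth + site
    below = np.clip(below_signal + rng.normal(0.0, cfg.below_noise_sd, n), 0.0, None)
    above_signal = (ABOVE_INTERCEPT
                    + ABOVE_BIOMASS_SLOPE * df["aboveground_biomass"]
                    + ABOVE_TREE_SLOPE * df["tree_cover"]).to_numpy()
    above = np.clip(above_signal + rng.normal(0.0, cfg.above_noise_sd, n), 0.0, None)

    df["burn_depth"] = depth
    df["belowground_cc"] = below
    df["aboveground_cc"] = above

    if truth is not None:
        truth.plot_truth = pd.DataFrame({
            "region": region, "depth_signal": depth_signal,
            "below_signal": below_signal, "above_signal": above_signal,
        })
    return df


def simulate_climate_series(cfg: SimConfig, truth: GroundTruth | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly climate (1958-2023) plus an annual fire table (2001-2023).

    Annual peat burned area follows ``exp(a + b*z)`` times lognormal noise,
    where ``z`` is the summer water-deficit z-score against the 1958-2023
    baseline exactly as the climate-statistics module computes it.  DC/DMC
    rise with water deficit; PDSI and soil moisture fall; minimum
    temperature rises weakly.  The link coefficients are recorded in
    ``truth.climate_truth`` for round-trip recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 202]))
    y0, y1 = BASELINE_YEARS
    years = np.arange(y0, y1 + 1)
    wd_annual = rng.normal(50.0, 15.0, len(years))

    month_offsets = {
        "water_deficit": np.array([-30, -28, -20, -8, 5, 18, 25, 22, 8, -5, -18, -26]),
        "tmin": np.array([-30, -28, -20, -8, 2, 8, 12, 10, 3, -6, -18, -26]),
    }
    rows = []
    wdc = wd_annual - wd_annual.mean()
    dc_a = 200.0 + 2.0 * wdc + rng.normal(0, 15.0, len(years))
    dmc_a = 60.0 + 0.8 * wdc + rng.normal(0, 6.0, len(years))
    pdsi_a = -0.08 * wdc + rng.normal(0, 0.6, len(years))
    sm_a = 0.30 - 0.002 * wdc + rng.normal(0, 0.02, len(years))
    tmin_a = 8.0 + 0.03 * wdc + rng.normal(0, 1.0, len(years))
    for i, year in enumerate(years):
        for m in range(1, 13):
            rows.append({
                "year": int(year), "month": m,
                "water_deficit": wd_annual[i] + month_offsets["water_deficit"][m - 1]
                + rng.normal(0, 2.0),
                "dc": max(dc_a[i] + rng.normal(0, 5.0), 0.0),
                "dmc": max(dmc_a[i] + rng.normal(0, 2.0), 0.0),
                "pdsi": pdsi_a[i] + rng.normal(0, 0.2),
                "soil_moisture": sm_a[i] + rng.normal(0, 0.01),
                "tmin": tmin_a[i] + month_offsets["tmin"][m - 1] + rng.normal(0, 1.0),
            })
    monthly = pd.DataFrame(rows)

    # summer-mean z-scores exactly as the analysis computes them (Jun-Sep)
    summer = (monthly[monthly["month"].isin([6, 7, 8, 9])]
              .groupby("year")["water_deficit"].mean())
    z_all = (summer - summer.mean()) / summer.std(ddof=1)
    fy = np.arange(FIRE_YEARS[0], FIRE_YEARS[1] + 1)
    z = z_all.loc[fy].to_numpy()
    log_noise = rng.normal(0.0, cfg.climate_log_noise_sd, len(fy))
    peat_ba = np.exp(cfg.climate_a + cfg.climate_b * z + log_noise)
    total_ba = peat_ba / 0.33 * np.exp(rng.normal(0.0, 0.15, len(fy)))
    annual = pd.DataFrame({
        "year": fy, "z_water_deficit": z,
        "peat_ba_mha": peat_ba, "total_ba_mha": total_ba,
    })
    if truth is not None:
        truth.climate_truth = {
            "a": cfg.climate_a, "b": cfg.climate_b,
            "log_noise_sd": cfg.climate_log_noise_sd,
        }
    return monthly, annual


#: Causal coefficients of the synthetic zone-level climate-fire system.
SEM_TRUTH = {
    ("water_deficit", "dc"): 0.66,
    ("tmin", "dc"): -0.30,
    ("water_deficit", "pdsi"): -0.85,
    ("dc", "log_total_ba"): 0.60,
    ("dc", "log_peat_ba"): 0.45,
    ("pdsi", "log_peat_ba"): -0.45,
    ("log_peat_ba", "below_cc"): 0.50,
    ("water_deficit", "below_cc"): 0.30,
}


def simulate_zone_climate(cfg: SimConfig, truth: GroundTruth | None = None,
                          n_years: int = 23, zone_sd: float = 0.3,
                          seed_offset: int = 0) -> pd.DataFrame:
    """Zone-by-year table generated from the causal graph in ``SEM_TRUTH``.

    Three geographic zones (west/central/east) with 23 years each; fire and
    combustion nodes carry zone random intercepts so mixed models are the
    appropriate fit, while the DC and PDSI paths are purely fixed-effect.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed, 303, seed_offset]))
    zones = ["west", "central", "east"]
    rows = []
    re = {node: {z: rng.normal(0, zone_sd) for z in zones}
          for node in ("dc", "log_total_ba", "log_peat_ba", "below_cc")}
    t = SEM_TRUTH
    for zone in zones:
        for year in range(FIRE_YEARS[0], FIRE_YEARS[0] + n_years):
            wd = rng.normal()
            tmin = rng.normal()
            dc = (t[("water_deficit", "dc")] * wd + t[("tmin", "dc")] * tmin
                  + re["dc"][zone] + rng.normal(0, 0.62))
            pdsi = t[("water_deficit", "pdsi")] * wd + rng.normal(0, 0.53)
            total = (t[("dc", "log_total_ba")] * dc
                     + re["log_total_ba"][zone] + rng.normal(0, 0.74))
            peat = (t[("dc", "log_peat_ba")] * dc
                    + t[("pdsi", "log_peat_ba")] * pdsi
                    + re["log_peat_ba"][zone] + rng.normal(0, 0.53))
            below = (t[("log_peat_ba", "below_cc")] * peat
                     + t[("water_deficit", "below_cc")] * wd
                     + re["below_cc"][zone] + rng.normal(0, 0.60))
            rows.append({
                "zone": zone, "year": year, "water_deficit": wd, "tmin": tmin,
                "dc": dc, "pdsi": pdsi, "log_total_ba": total,
                "log_peat_ba": peat, "below_cc": below,
            })
    if truth is not None:
        truth.sem_truth = dict(SEM_TRUTH)
    return pd.DataFrame(rows)


def predictor_rasters(cfg: SimConfig, truth: GroundTruth, year: int,
                      names=ABOVE_PREDICTORS) -> dict[str, np.ndarray]:
    """Per-pixel predictor rasters consistent with the field-plot generator.

    Static fields come from the landscape's smooth base fields; the
    ``water_deficit`` raster is the year's domain z-score plus small spatial
    texture.  Used to drive pixel-scale combustion prediction.
    """
    h, w = truth.grid.shape
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 404, year]))
    out: dict[str, np.ndarray] = {}
    for name in names:
        if name == "water_deficit":
            out[name] = (truth.water_deficit_z.get(year, 0.0)
                         + 0.15 * _smooth_field(rng, (h, w), 10.0))
        else:
            out[name] = np.asarray(truth.base_fields[name], dtype=float)
    return out


def true_depth_raster(truth: GroundTruth, rasters: dict[str, np.ndarray]) -> np.ndarray:
    """Noise-free burn-depth surface implied by the generator's linear link."""
    c = DEPTH_COEF
    return np.clip(
        c["intercept"]
        + c["soil_carbon_density"] * rasters["soil_carbon_density"]
        + c["water_deficit"] * rasters["water_deficit"]
        + c["tree_cover"] * rasters["tree_cover"],
        0.5, None)


def planted_regression(n: int = 300, n_features: int = 20, n_informative: int = 3,
                       noise_sd: float = 0.5, seed: int = 0
                       ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Regression toy with a few informative features, for selection tests."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, n_features)),
                     columns=[f"f{i:02d}" for i in range(n_features)])
    informative = list(X.columns[:n_informative])
    coefs = np.linspace(2.0, 1.0, n_informative)
    y = X[informative].to_numpy() @ coefs + rng.normal(0, noise_sd, n)
    return X, y, informative
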