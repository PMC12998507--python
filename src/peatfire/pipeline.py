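"""End-to-end desk-scale pipeline over a synthetic landscape.

Chains every stage: scene simulation, min-NBR compositing, random-forest
classification trained on one reference year, seed/growing/morphology
refinement, active-fire fusion with Voronoi dating and year relocation,
fire-patch clustering with overwintering flags, peatland downscaling and
peat-fire attribution, combustion modeling with GP uncertainty, and the
climate-fire statistics.  Used by the test suite and the reproduction
script; every stage is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from peatfire import active_fire, classifier, composites, emissions, gp
from peatfire import patches as patch_mod
from peatfire import peatland, postprocess, synthetic
from peatfire.classifier import AccuracyReport
from peatfire.synthetic import GroundTruth, SimConfig


@dataclass
class BurnedAreaResult:
    """Detected burned masks and dates per fire year, plus diagnostics."""

    burned: dict[int, np.ndarray]
    burn_day: dict[int, np.ndarray]
    seeds: dict[int, np.ndarray]
    relocated: dict[int, np.ndarray]
    accuracy: AccuracyReport
    accuracy_by_year: dict[int, AccuracyReport]


@dataclass
class PipelineResult:
    cfg: SimConfig
    truth: GroundTruth
    ba: BurnedAreaResult
    patches: dict[int, list]
    peat_mask: np.ndarray
    peat: peatland.PeatFireResult
    patch_table: pd.DataFrame
    emissions_table: pd.DataFrame | None = None
    bundle: emissions.ModelBundle | None = None
    uncertainty: list[gp.AnnualUncertainty] = field(default_factory=list)
    climate_fit: object | None = None
    sem_fit: object | None = None
    relocation_stats: dict | None = None


def _training_samples(truth: GroundTruth, year: int, n_per_class: int,
                      rng: np.random.Generator) -> list[classifier.TrainingSample]:
    """Small quadrilateral samples drawn from the truth of the reference year.

    Burned polygons sit inside that year's scars; unburned polygons sample
    the rest of the landscape (old burns, vegetation, peat — everything but
    open water and the current scars).
    """
    h, w = truth.grid.shape
    scar = truth.scar_mask[year]
    unburned_ok = ~scar & ~truth.water_mask
    samples = []
    for label, mask in ((1, scar), (0, unburned_ok)):
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            continue
        count = 0
        tries = 0
        while count < n_per_class and tries < n_per_class * 30:
            tries += 1
            k = int(rng.integers(rr.size))
            half = int(rng.integers(1, 4))
            r0, r1 = max(rr[k] - half, 0), min(rr[k] + half + 1, h)
            c0, c1 = max(cc[k] - half, 0), min(cc[k] + half + 1, w)
            block = mask[r0:r1, c0:c1]
            if not block.all():
                continue
            br, bc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                                 indexing="ij")
            samples.append(classifier.TrainingSample(
                rows=br.ravel(), cols=bc.ravel(), label=label, year=year))
            count += 1
    return samples


def map_burned_area(cfg: SimConfig, stacks, truth: GroundTruth,
                    reference_year: int | None = None,
                    n_samples_per_class: int = 60,
                    seed: int | None = None) -> BurnedAreaResult:
    """Classify, refine, fuse active fires and relocate years for all years."""
    seed = cfg.rng_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    years = cfg.fire_years
    comps = {y: composites.min_nbr_composite(stacks[y])
             for y in [years[0] - 1] + years}
    feats = {y: composites.build_feature_stack(comps[y - 1], comps[y])
             for y in years}

    # Reference year for training: the last fire year, whose landscape
    # already contains older scars, so the unburned class spans vegetation
    # AND previously burned surfaces (only the pre/post difference separates
    # a fresh burn from an old one).
    ref = reference_year if reference_year is not None else years[-1]
    samples = _training_samples(truth, ref, n_samples_per_class, rng)
    X, y_lab = classifier.extract_training_matrix(samples, feats)
    clf = classifier.train_rf(X, y_lab, seed=seed)

    af = truth.af_records
    burned: dict[int, np.ndarray] = {}
    burn_day: dict[int, np.ndarray] = {}
    seeds: dict[int, np.ndarray] = {}
    relocated: dict[int, np.ndarray] = {}
    for yy in years:
        pb = classifier.predict_probability(clf, feats[yy])
        refined, seed_mask = postprocess.refine(
            pb, feats[yy], burned_train_mean_pb=clf.burned_train_mean_pb)
        af_y = af[af["year"] == yy]
        af_raster = active_fire.rasterize_active_fires(af_y, truth.grid)
        refined = active_fire.append_af_pixels(refined, af_raster,
                                               truth.water_cover)
        day, _ = active_fire.assign_dates_voronoi(
            refined, af_y, truth.grid,
            fallback_day=feats[yy].post_day.astype(float))
        burned[yy] = refined
        burn_day[yy] = day
        seeds[yy] = seed_mask.seeds

    # late-season detections surfacing a year late are moved back
    for yy in years:
        relocated[yy] = np.zeros(truth.grid.shape, dtype=bool)
    for yy in years[1:]:
        move = active_fire.relocate_year(
            burned[yy], af[af["year"] == yy - 1], af[af["year"] == yy],
            truth.grid)
        move &= ~burned[yy - 1]
        if move.any():
            prev_day, _ = active_fire.assign_dates_voronoi(
                move, af[af["year"] == yy - 1], truth.grid)
            burned[yy - 1] = burned[yy - 1] | move
            burn_day[yy - 1] = np.where(move, prev_day, burn_day[yy - 1])
            burned[yy] = burned[yy] & ~move
            burn_day[yy] = np.where(move, np.nan, burn_day[yy])
            relocated[yy] = move

    by_year = {}
    tp = fp = fn = tn = 0
    for yy in years:
        rep = classifier.evaluate_against_reference(
            burned[yy], truth.scar_mask[yy])
        by_year[yy] = rep
        tp, fp, fn, tn = tp + rep.tp, fp + rep.fp, fn + rep.fn, tn + rep.tn
    pooled = AccuracyReport(tp=tp, fp=fp, fn=fn, tn=tn)
    return BurnedAreaResult(burned=burned, burn_day=burn_day, seeds=seeds,
                            relocated=relocated, accuracy=pooled,
                            accuracy_by_year=by_year)


def relocation_performance(cfg: SimConfig, truth: GroundTruth,
                           ba: BurnedAreaResult) -> dict:
    """How many late-season planted pixels were moved to their true year."""
    n_true = n_moved = 0
    for yy in cfg.fire_years[:-1]:
        late = truth.scar_table[(truth.scar_table["year"] == yy)
                                & (truth.scar_table["kind"] == "late")]
        if late.empty:
            continue
        for _, s in late.iterrows():
            # this scar's pixels, via the truth table geometry
            rr, cc = np.nonzero(truth.scar_mask[yy])
            d = np.hypot(rr - s["row"], cc - s["col"])
            keep = d <= max(cfg.scar_size_range) + 2
            rr, cc = rr[keep], cc[keep]
            next_mask = ba.burned.get(yy + 1, np.zeros(truth.grid.shape, bool))
            detected = ba.burned[yy][rr, cc] | next_mask[rr, cc]
            in_true_year = ba.burned[yy][rr, cc]
            n_true += int(detected.sum())
            n_moved += int((in_true_year & detected).sum())
    return {"n_late_detected": n_true, "n_in_true_year": n_moved,
            "fraction_relocated": n_moved / n_true if n_true else np.nan}


def run_pipeline(cfg: SimConfig, coarse_block: int = 32,
                 run_emissions: bool = True, run_climate: bool = True,
                 emissions_budget: int = 8, emissions_repeats: int = 5,
                 emissions_folds: int = 5, rfe: bool = False,
                 gp_inducing: int | None = 200) -> PipelineResult:
    """Run the full chain on one synthetic landscape.

    Desk-scale defaults keep the run light: a reduced hyperparameter budget,
    5 CV repeats and no feature elimination in the combustion stage (full
    selection is exercised separately), and a 200-point inducing set for the
    uncertainty GP.
    """
    stacks, truth = synthetic.simulate_scenes(cfg)
    ba = map_burned_area(cfg, stacks, truth)
    reloc = relocation_performance(cfg, truth, ba)

    # peatland: downscale a coarse area map derived from the truth mask
    labels = peatland.block_labels(truth.grid.shape, coarse_block)
    areas = peatland.coarse_areas_from_mask(truth.peat_mask, labels,
                                            truth.grid.pixel_area)
    peat_map = peatland.PeatIndexMap(index=truth.peat_index,
                                     unit_labels=labels,
                                     unit_area_m2=areas, grid=truth.grid)
    peat_mask = peatland.downscale_peat(peat_map)
    peat = peatland.classify_peat_fires(ba.burned, peat_mask,
                                        pixel_area=truth.grid.pixel_area)

    # fire patches with overwintering flags
    all_patches: dict[int, list] = {}
    prev = []
    for yy in cfg.fire_years:
        pts = patch_mod.cluster_patches(ba.burn_day[yy], year=yy,
                                        pixel_size=cfg.pixel_size)
        patch_mod.attach_peat_fraction(pts, peat_mask)
        patch_mod.attach_seed_counts(pts, ba.seeds[yy])
        patch_mod.flag_overwintering(pts, prev, peat_mask=peat_mask)
        all_patches[yy] = pts
        prev = pts
    patch_table = pd.concat(
        [patch_mod.patch_summaries(p) for p in all_patches.values()],
        ignore_index=True)

    result = PipelineResult(cfg=cfg, truth=truth, ba=ba, patches=all_patches,
                            peat_mask=peat_mask, peat=peat,
                            patch_table=patch_table,
                            relocation_stats=reloc)

    if run_emissions:
        plots = synthetic.simulate_field_plots(cfg, truth)
        seed = cfg.rng_seed
        depth_sel = emissions.tune_and_select(
            plots, "burn_depth", list(synthetic.DEPTH_PREDICTORS),
            budget=emissions_budget, folds=emissions_folds, seed=seed, rfe=rfe)
        below_sel = emissions.Selection(
            features=list(synthetic.INFORMATIVE_PREDICTORS)
            + [emissions.DEPTH_FEATURE],
            params=depth_sel.params, cv_rmse=np.nan)
        above_sel = emissions.tune_and_select(
            plots, "aboveground_cc", list(synthetic.ABOVE_PREDICTORS),
            budget=emissions_budget, folds=emissions_folds, seed=seed + 1,
            rfe=rfe)
        bundle = emissions.fit_evaluate(
            plots, depth_sel, below_sel, above_sel,
            folds=emissions_folds, repeats=emissions_repeats, seed=seed)
        result.bundle = bundle

        tables = []
        for yy in cfg.fire_years:
            rasters = synthetic.predictor_rasters(cfg, truth, yy)
            preds = emissions.predict_pixels(bundle, rasters, ba.burned[yy])
            tables.append(emissions.aggregate_emissions(
                preds, ba.burned[yy], peat.peat_fire[yy],
                pixel_area=truth.grid.pixel_area, year=yy))
            rr, cc = np.nonzero(ba.burned[yy])
            cc_total = (preds.belowground_cc + preds.aboveground_cc)[rr, cc]
            sigma = np.hypot(bundle.below_metrics.residual_sd,
                             bundle.above_metrics.residual_sd)
            mu = (bundle.below_metrics.residual_mean
                  + bundle.above_metrics.residual_mean)
            noise = gp.PixelVariance(
                sigma_cc=np.full(rr.size, sigma),
                area=np.full(rr.size, truth.grid.pixel_area))
            coords = truth.grid.pixel_centers(rr, cc)
            result.uncertainty.append(gp.annual_uncertainty(
                cc_total, coords, noise,
                cutoff=gp.DEFAULT_LENGTH_SCALE, m=gp_inducing,
                mu_res=mu, rng=seed + yy, year=yy))
        result.emissions_table = pd.concat(tables, ignore_index=True)

    if run_climate:
        from peatfire import climate as climate_mod

        monthly, annual = synthetic.simulate_climate_series(cfg, truth)
        anom = climate_mod.summer_anomalies(monthly,
                                            variables=["water_deficit"])
        z = anom.z_scores.loc[annual["year"], "water_deficit"].to_numpy()
        result.climate_fit = climate_mod.fit_exponential(
            annual["peat_ba_mha"].to_numpy(), z)
        zone = synthetic.simulate_zone_climate(cfg, truth)
        result.sem_fit = climate_mod.piecewise_sem(
            zone, climate_mod.default_sem_spec())
    return result
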