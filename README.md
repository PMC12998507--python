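# peatfire

Burned-area mapping, peat-fire attribution and fire carbon-emission
modeling for boreal and Arctic landscapes, with a seeded synthetic-landscape
generator so the entire chain runs and is tested offline at desk scale.

## The problem

Northern peatlands store vast soil organic carbon. When they burn, most of
the loss comes from smoldering combustion of organic soil ("peat fires"),
which coarse satellite fire products systematically miss. Quantifying peat
fires requires: (1) mapping burned area (BA) at fine (30 m) resolution from
multispectral image composites; (2) attributing burned pixels to peatland
using an area-conserving downscaling of a coarse peatland map; (3) grouping
burned pixels into dated fire events, including "zombie" fires that smolder
through winter and re-emerge the next spring near their origin; and
(4) converting burned area to carbon emissions through models of burn depth
and carbon combustion with honest uncertainty.

## What the package implements

- **Compositing** (`peatfire.composites`): spectral indices
  NDVI = (ρ_NIR − ρ_red)/(ρ_NIR + ρ_red),
  NBR = (ρ_NIR − ρ_SWIRL)/(ρ_NIR + ρ_SWIRL),
  NBR2 = (ρ_SWIRS − ρ_SWIRL)/(ρ_SWIRS + ρ_SWIRL); cloud/water quality
  filters; annual minimum-NBR composites and the 28-feature
  (9 post + 9 pre + 9 difference + date-difference) classification stack.
- **Classification** (`peatfire.classifier`): a 200-tree random forest
  (min leaf 10, ≤450 leaves, sqrt features, 50% bag fraction) trained on
  labeled polygons of one reference year; P_b = fraction of trees voting
  burned; omission/commission/Dice validation,
  Dice = 2TP/(2TP + FP + FN) = 2/(1/(1−E_o) + 1/(1−E_c)).
- **Refinement** (`peatfire.postprocess`): seeds with P_b above the burned
  training-class mean; region growing within 2 km of seeds under
  {P_b ≥ 40%} OR {NBR2_post ≤ 0.06 ∧ NBR2_diff ≤ 0.005 ∧ red_diff ≥ 0.04 ∧
  NIR_diff ≤ −0.003} OR {NBR2_post ≤ 0 ∧ NBR2_diff ≤ 0.01 ∧
  red_post ≤ 0.03}; patches with <4 seeds dropped; 3×3 (90 m) morphology.
- **Active-fire fusion** (`peatfire.active_fire`): footprint rasterization,
  Voronoi (nearest-detection) burn dating, Queen-contiguity appending of
  detections not dominated by water (<80% annual water cover), and
  relocation of late-season burns to the previous year when a previous-year
  detection lies within 5 km and closer than any current-year one.
- **Fire patches** (`peatfire.patches`): flood-fill clustering with a
  16-day cutoff and ~150-m bridging, windowed tile processing, and
  overwintering flags (start before July 1 within 1 km of last season's
  fires, edge to edge).
- **Peatland** (`peatfire.peatland`): within each coarse unit the
  highest-index fine pixels are selected until their area matches the
  coarse peat area; burned ∩ peat = peat fire.
- **Emissions** (`peatfire.emissions`): three XGBoost models — burn depth,
  belowground carbon combustion (consuming the *out-of-fold predicted*
  depth), aboveground combustion — with recursive feature elimination and a
  seeded 200-draw search over eight hyperparameters, evaluated by 10-fold
  CV repeated and averaged per plot.
- **Uncertainty** (`peatfire.gp`): Matérn-3/2 kernel
  k(d) = (1 + √3 d/ℓ) exp(−√3 d/ℓ), ℓ = 25 km with a hard correlation
  cutoff; heteroscedastic noise D = diag((σ_CC,i · A_i)²); posterior
  K_post = K − K(K + D)⁻¹K; Nyström low-rank form K̃ = K_nm K_mm⁻¹ K_mn
  (O(m²n), 1000 inducing points per batch at full scale); annual variance
  sᵀK_post s with s_i = σ_CC,i·A_i.
- **Climate statistics** (`peatfire.climate`): summer (Jun–Sep) z-score
  anomalies against a 1958–2023 baseline; exponential fits
  log BA = a + b·z; Mann–Kendall trend test with Sen slope; piecewise SEM
  with zone-level mixed models, marginal/conditional R² and Fisher's
  C = −2Σln p over the d-separation basis set.
- **Synthetic landscapes** (`peatfire.synthetic`): seeded scenes with
  vegetated/burned/water/cloud archetypes, elliptical scars with per-pixel
  ignition days, active fires sampled on the fire front, overwintering and
  late-season scars planted with known truth, field plots with a
  depth–combustion link calibrated to r = 0.75, and an exponential
  climate–fire link with known coefficients.

## Worked example

```python
from peatfire.synthetic import SimConfig
from peatfire.pipeline import run_pipeline

res = run_pipeline(SimConfig(grid_height=128, grid_width=128, years=3,
                             rng_seed=1))
rep = res.ba.accuracy
print(f"omission {rep.omission_error:.2f}%  commission "
      f"{rep.commission_error:.2f}%  dice {rep.dice:.3f}")
print(res.peat.annual[["year", "peat_fraction"]])
print(f"depth model R2 = {res.bundle.depth_metrics.r2:.2f}")
print(f"climate fit: b = {res.climate_fit.b:.2f}, R2 = {res.climate_fit.r2:.2f}")
```

prints (seed 1):

```
omission 1.42%  commission 1.26%  dice 0.987
   year  peat_fraction
0  2015       0.219048
1  2016       0.669927
2  2017       0.527778
depth model R2 = 0.44
climate fit: b = 0.53, R2 = 0.88
```

That is: the pipeline recovers 98.6% of true scar pixels with 1.3%
commission; the per-year fraction of burned area on peat matches the
generator's truth (0.219/0.672/0.529) to a fraction of a percent; the burn
depth model explains ~0.44 of plot variance under the generator's field
noise; and the exponential climate fit recovers the planted slope b = 0.5.

A thin CLI wraps the same calls: `peatfire simulate --out dir/`,
`peatfire pipeline --seed 1 --out dir/`, and
`peatfire stats trend|expfit` on CSV tables.

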