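# Methods

This note documents the models, rules and numerical choices behind
`peatfire`, and what the synthetic-data tests do and do not demonstrate.

## Grid and units

All rasters live on a planar grid of square 30-m pixels; pixel (i, j) has
its center at ((j+0.5)·30, (i+0.5)·30) meters. Every metric rule — the
150-m patch bridging, the 1-km overwintering vicinity, the 2-km
growing-region vicinity, the 5-km relocation radius, the 25-km kernel
cutoff — is evaluated in meters on this grid. Using a planar stand-in for a
geographic grid removes projection machinery while preserving each rule
exactly; nothing in the algorithms depends on curvature at these scales.

## Burned-area mapping

A year's observations are filtered per scene (drop when SWIRL > 0.3 or
NIR > 0.33, cloud saturation; red or NIR < 0.005, open water; NBR2 < −0.3
for Landsat-5 scenes of 2001/2002, a stripe artifact) and reduced to the
observation minimizing NBR, the strongest burn signal. Ties on NBR take the
earliest day, so compositing is deterministic. Pre- and post-year
composites are differenced into 28 features: the only decomposition
consistent with that count is 9 post + 9 pre + 9 difference features (six
bands plus NDVI/NBR/NBR2) plus one date-difference band; the pre-composite
uses the same March–November window.

The classifier is a 200-tree random forest with a minimum leaf population
of 10, at most 450 leaves per tree, sqrt feature subsampling and a 50%
bootstrap fraction. The "maximum nodes" budget is mapped to scikit-learn's
`max_leaf_nodes` (450 leaves ⇒ ≤899 nodes in a binary tree) — tree
libraries parameterize size differently and the leaf budget is the closest
binding constraint. Burn probability is the fraction of trees voting
burned, not the averaged leaf class frequencies; with impure 10-observation
leaves the two differ. Training rows are canonically sorted before fitting
so sample order cannot change the model under a fixed seed. The model is
trained once on a reference year and reused: the fire signal is assumed
independent of time. The reference year defaults to the **last** fire year
so that the unburned class includes old burn scars, which only the
difference features separate from fresh burns; training on a year with no
burn history re-detects old scars in every later year.

Refinement follows four rules in order: seeds are classified pixels whose
probability strictly exceeds the mean probability of the burned training
class; the growing region adds pixels satisfying the relaxed spectral
disjunction, within 2 km of the *nearest* seed, and 8-connected to the
evolving region, iterated to a fixed point (convergence makes the result
independent of visit order, and contiguity — not proximity alone —
prevents flooding disconnected qualifying pixels); connected patches with
fewer than four seeds are discarded; and a 3×3 (90 m) morphological pass is
applied literally as dilation–erosion then erosion–dilation (the
operator-definition convention is followed as stated even though it swaps
the standard naming; the net effect is closing-then-opening: holes fill,
isolated pixels vanish). The "90 mm" kernel dimension is read as a typo for
90 m.

## Active-fire fusion

Detections paint rectangles given by their per-record along/cross-track
footprints; overlaps keep the earliest day. Burn dates are reassigned from
the nearest detection (Voronoi cells; ties take the earlier day), replacing
all composite dates — the composite date survives as a fallback only when a
year has no detections, flagged low-confidence. Detections Queen-connected
to a patch are appended when annual water cover is below 80% (per pixel,
not patch mean: the rule is stated per pixel), iterated so chains attach.
A pixel detected in year t is relocated to year t−1 iff a previous-year
detection lies within 5 km (inclusive) and strictly closer than every
current-year detection.

## Fire patches and overwintering

Flood-fill clustering joins pixels connected by chains of neighbor pairs —
8-connectivity extended to any pixels within ~150 m (bridging rivers) —
whose burn days differ by ≤16 days (the optimum within the 12–24-day range
appropriate to slowly spreading, cloud-obscured boreal fires). Tiled
processing clusters each tile within a rolling 3×3-tile window and
deduplicates by pixel-set identity; it equals whole-raster clustering for
patches smaller than one tile span. Patch start/end days are min/max pixel
days. A patch is overwintering when it starts before July 1 (day 182;
183 in leap years; boundary exclusive) within 1 km — measured edge-to-edge
between pixel sets, since holdover fires re-emerge at perimeters — of a
previous-season patch; the linkage records the nearest origin and whether
peatland occurs in the corridor (pixels within 1 km of both patches).

## Peatland downscaling

Within each coarse unit (rectangular cells here; irregular regions via a
labeled raster), fine pixels are selected in decreasing index order until
the selected area matches the coarse peat area, rounding the pixel count to
nearest (area conserved to half a fine pixel per unit); index ties break by
flat pixel order. The peatland-plausibility index itself is an input, never
fitted here.

## Combustion models

Three gradient-boosted models over field plots: burn depth (cm) from up to
42 predictors; belowground combustion (g C m⁻²) from a reduced set plus the
**averaged out-of-fold depth prediction** — never the observed depth and
never an in-fold prediction, so the chained feature carries no leakage;
aboveground combustion from 43 predictors including biomass. Selection
runs recursive feature elimination first (rank by gain importance on the
full fit, drop the least important, score every nested subset by K-fold CV
RMSE; ties prefer fewer features, and exact duplicate columns are reduced
to their first occurrence before elimination), then a seeded random search
over eight hyperparameters (learning rate, tree depth, min child weight,
row/column subsampling, L1, L2, boosting rounds) with a 200-draw budget
minimizing the same CV RMSE. The search is a budgeted random draw rather
than an adaptive optimizer: with the budget and objective fixed, the
optimizer's identity does not affect what the analysis claims. Evaluation
averages out-of-fold predictions over repeated K-fold splits (100 repeats
at full scale; desk-scale runs use 5 repeats and 5 folds) before computing
R², RMSE and relative bias ((mean pred − mean obs)/mean obs; the mean
pixelwise ratio is reported alongside). Residual means and standard
deviations from those averaged predictions feed the uncertainty model. At
pixel scale the chained depth is the depth model's direct prediction (no
CV averaging exists at prediction time), and negative predictions are
floored at zero with a logged count.

## Uncertainty propagation

Combustion residuals are modeled as a spatially correlated Gaussian field
over each year's burned pixels with Matérn-3/2 correlation
k(d) = (1+√3·d/ℓ)exp(−√3·d/ℓ), ℓ = 25 km (the coarsest predictor
resolution); correlations beyond ℓ are set to zero by a hard cutoff. The
cutoff technically breaks positive semi-definiteness, so a 1e−8 jitter
backs every factorization. The posterior at the burned pixels is
K_post = K − K(K+D)⁻¹K with heteroscedastic noise D = diag((σ_CC,i·A_i)²),
σ_CC,i the residual standard deviation of the relevant combustion model
(constant per model per run, with a hook for per-pixel inflation) and A_i
the pixel area. The annual total's variance is sᵀK_post s with
s_i = σ_CC,i·A_i: the unit-variance posterior carries the correlation
structure and s carries the g C amplitude, which keeps the variance in
(g C)² while reducing to the sum of scaled pixelwise posterior variances as
ℓ→0 and to zero when residual noise is zero. The residual mean is applied
as a bias correction to totals before reporting. For large pixel counts
the Gram matrix is replaced by its Nyström reconstruction
K̃ = K_nm K_mm⁻¹ K_mn from m inducing pixels sampled uniformly per
processing batch (1000 per batch at full scale; 200 at desk scale),
combined with the Woodbury identity so cost stays O(m²n); batches are
treated as independent beyond the cutoff.

## Climate statistics

Summer means average June–September (early and late season included).
Anomalies are z-scores against the 1958–2023 baseline (66 years; a
baseline must span ≥30 years, and a zero baseline standard deviation is an
error, not a silent NaN). The climate–fire relation is fitted as ordinary
least squares on log BA by default (a log-link Gaussian GLM on the raw
response is available); zero-BA years are offset by half the smallest
positive value, recorded in the fit. The Mann–Kendall test uses the
tie-corrected variance and ±1 continuity correction, with the Sen slope as
the median pairwise slope. The piecewise SEM standardizes all variables by
grand standard deviations (so coefficients are standardized betas), fits
each endogenous node with a zone-random-intercept mixed model by restricted
likelihood — except the DC and PDSI nodes, which use plain regression —
and reports marginal R² (fixed-effect variance over fixed + random +
residual) and conditional R² (fixed + random over the same denominator).
Degenerate random variances are reported, and an unidentifiable mixed model
falls back to ordinary regression with a warning. The d-separation basis
set contains every non-adjacent node pair except declared correlated-error
pairs and pairs of exogenous nodes (whose covariance is free); each claim
conditions on the union of both nodes' parents and is tested within the
downstream node's model family. Fisher's C = −2Σln p is compared to
chi-square with 2k degrees of freedom. The covariance of the endogenous
burned-area pair is reported both as the raw correlation and as the
correlation of model residuals, since either reading is defensible.

## The synthetic landscape

The generator emulates exactly what the pipeline needs and no more.
Reflectance is four archetypes (vegetated, burned, water, cloud) plus
Gaussian noise (σ = 0.008): burning drops NIR (0.30→0.08) and raises long
SWIR (0.10→0.25), clouds exceed the NIR/SWIRL filter caps, water sits
below the red/NIR floor. Scars are ellipses whose fronts expand linearly
over 15–35 days, giving each pixel an ignition day; burned pixels stay
spectrally burned in later years, so only first-year differences are
classifiable — as in reality. From the second fire year on, one scar per
year ignites in mid-June within 90–600 m of a previous-year scar
(overwintering truth), and one scar per year (except the last) ignites
after the season's last scene so its spectral signal appears only the next
year (relocation truth). Active-fire points sample the expanding front
every 3 days with ±10 m jitter; footprints are per-record, capped at the
nominal 375 m and shrunk to the locally burned extent near scar edges so a
detection's painted rectangle stays inside the truth scar. Real detections
overhang scar edges and inflate commission — a sensor property, not a
landscape property, and one the pipeline tolerates rather than a truth the
generator should encode.

Field plots: depth = 2 + 0.25·soilC + 1.8·wd_z + 0.05·treeCover + ε with
ε ~ N(0, 3.2²), leaving about half the depth variance explainable —
matching realistic field predictability; belowground combustion
= 500 + 250·depth + site + ε with the site/noise spread calibrated so
r(depth, belowground) = 0.75; region labels follow 285:568:41
Alaska:Canada:Siberia proportions by largest remainder. The climate series
draws 66 years of water deficit, derives z-scores exactly as the analysis
will, and sets peat BA = exp(a + b·z + ε) with a = 0, b = 0.5 and
ε ~ N(0, 0.2²). That noise level implies a log-scale R² near 0.86 — the
Arctic-strength climate sensitivity — because at n = 23 years a weaker
link leaves the slope unrecoverable to ±20% with high probability; the
generator therefore emulates the Arctic regime, where the climate–fire
coupling is strongest. The zone-level SEM table is generated from the
causal graph itself with known coefficients and zone intercepts.

What passing tests show: every rule and formula behaves as specified,
oracle-equivalently where an independent oracle exists, and the chain
recovers planted truth under clean spectral separability. What they do not
show: performance under mixed pixels, sensor calibration drift, real cloud
morphology, fuel heterogeneity, or geolocation error — the archetype
landscape has none of these, so synthetic accuracy (Dice ≈ 0.99) is an
upper bound, not a forecast of accuracy on real imagery (Dice ≈ 0.8 in
comparable real-data validations).

## Problem sizes

Desk-scale defaults: 128×128 pixels × 3 fire years (plus one spin-up
year), ~18 scenes per year, 894 field plots, 5-fold/5-repeat CV with a
reduced hyperparameter budget, 200 GP inducing points, 23-year climate
series with a 66-year baseline. These sizes exercise every code path,
including the windowed tile merge and the Nyström path, while an
end-to-end run stays under a minute; the full-scale defaults (10-fold,
100 repeats, 200-draw budget, 1000 inducing points) remain the library
defaults of the respective functions.
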