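"""Gradient-boosted burn-depth and carbon-combustion models.

Three chained models over field combustion plots: burn depth (cm) from up
to 42 candidate predictors; belowground carbon combustion (g C m⁻²) from a
reduced predictor set plus the *out-of-fold* depth prediction (burn depth
is the dominant control on smoldering losses, so the predicted depth — never
the observed one — enters the combustion model); and aboveground carbon
combustion from a 43-predictor set that adds aboveground biomass.

Model selection combines recursive feature elimination (nested subsets
scored by 10-fold cross-validated RMSE) with a seeded, budgeted random
search over eight boosting hyperparameters (200 draws by default,
minimizing the same CV RMSE).  Evaluation uses 10-fold predictions repeated
(100 repeats at full scale), averaged per plot before computing R², RMSE
and relative bias; residual statistics from those averaged out-of-fold
predictions feed the uncertainty propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

#: The eight tuned boosting hyperparameters and their search ranges.
HYPERPARAM_SPACE = {
    "learning_rate": ("log", 0.01, 0.3),
    "max_depth": ("int", 2, 8),
    "min_child_weight": ("log", 1.0, 20.0),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample_bytree": ("uniform", 0.5, 1.0),
    "reg_alpha": ("log", 1e-3, 1.0),
    "reg_lambda": ("log", 1e-2, 10.0),
    "n_estimators": ("int", 50, 400),
}

DEFAULT_PARAMS = {
    "learning_rate": 0.05,
    "max_depth": 4,
    "min_child_weight": 4.0,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "reg_alpha": 0.01,
    "reg_lambda": 1.0,
    "n_estimators": 200,
}

#: Column name under which the chained depth prediction enters the
#: belowground model.
DEPTH_FEATURE = "predicted_burn_depth"


def _make_model(params: dict, seed: int) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        objective="reg:squarederror",
        random_state=int(seed) % (2**31),
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        **params,
    )


def sample_hyperparams(rng: np.random.Generator) -> dict:
    """Draw one configuration from :data:`HYPERPARAM_SPACE`."""
    out = {}
    for name, (kind, lo, hi) in HYPERPARAM_SPACE.items():
        if kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        elif kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def _cv_rmse(X: np.ndarray, y: np.ndarray, params: dict, folds: int,
             seed: int) -> float:
    """Average RMSE over a seeded K-fold split."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    errs = []
    for tr, te in kf.split(X):
        model = _make_model(params, seed)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return float(np.mean(errs))


@dataclass
class Selection:
    """Outcome of feature selection + hyperparameter search for one target."""

    features: list[str]
    params: dict
    cv_rmse: float
    rfe_path: list[tuple[int, float]] = field(default_factory=list)
    search_history: list[tuple[dict, float]] = field(default_factory=list)


def tune_and_select(plots: pd.DataFrame, target: str,
                    candidate_features: list[str], budget: int = 200,
                    folds: int = 10, seed: int = 0,
                    rfe: bool = True) -> Selection:
    """Recursive feature elimination plus budgeted hyperparameter search.

    RFE runs first with baseline hyperparameters: features are ranked by
    ensemble gain importance on the full data, the least important is
    dropped, and every nested subset is scored by K-fold CV RMSE; the
    subset minimizing RMSE wins (ties prefer fewer features; duplicated
    columns split importance, so exactly one of a duplicated pair survives
    the elimination order).  The hyperparameter search then draws up to
    ``budget`` seeded configurations on the selected subset and keeps the
    CV-RMSE minimizer.
    """
    if budget < 1:
        raise ValueError("hyperparameter search budget must be >= 1")
    if len(candidate_features) < 2:
        raise ValueError("need at least two candidate features")
    if len(plots) < 50:
        raise ValueError("need at least 50 plots")
    y = plots[target].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # exactly one of any set of identical columns enters the elimination:
    # duplicates split ensemble importance arbitrarily, so the tie-break is
    # "keep the first occurrence"
    features = []
    seen_cols: list[np.ndarray] = []
    for name in candidate_features:
        col = plots[name].to_numpy(dtype=float)
        if any(np.array_equal(col, c) for c in seen_cols):
            continue
        seen_cols.append(col)
        features.append(name)
    best_features = list(features)
    rfe_path: list[tuple[int, float]] = []
    if rfe:
        best_rmse = np.inf
        current = list(features)
        while len(current) >= 1:
            X = plots[current].to_numpy(dtype=float)
            rmse = _cv_rmse(X, y, DEFAULT_PARAMS, folds, seed)
            rfe_path.append((len(current), rmse))
            # ties prefer fewer features: <= keeps the smaller subset
            if rmse <= best_rmse:
                best_rmse = rmse
                best_features = list(current)
            if len(current) == 1:
                break
            model = _make_model(DEFAULT_PARAMS, seed)
            model.fit(X, y)
            imp = model.feature_importances_
            drop = int(np.argmin(imp))  # first minimum: deterministic tie-break
            current.pop(drop)

    X_sel = plots[best_features].to_numpy(dtype=float)
    history: list[tuple[dict, float]] = []
    best_params, best_rmse = dict(DEFAULT_PARAMS), np.inf
    for _ in range(int(budget)):
        params = sample_hyperparams(rng)
        rmse = _cv_rmse(X_sel, y, params, folds, seed)
        history.append((params, rmse))
        if rmse < best_rmse:
            best_params, best_rmse = params, rmse
    return Selection(features=best_features, params=best_params,
                     cv_rmse=best_rmse, rfe_path=rfe_path,
                     search_history=history)


@dataclass
class ModelMetrics:
    """Repeated-CV evaluation of one model on averaged out-of-fold predictions."""

    r2: float
    rmse: float
    relative_bias: float
    relative_bias_ratio_mean: float
    residual_mean: float
    residual_sd: float
    oof_prediction: np.ndarray


@dataclass
class ModelBundle:
    """The three fitted models with their selections and CV metrics."""

    depth_model: xgb.XGBRegressor
    below_model: xgb.XGBRegressor
    above_model: xgb.XGBRegressor
    depth_selection: Selection
    below_selection: Selection
    above_selection: Selection
    depth_metrics: ModelMetrics
    below_metrics: ModelMetrics
    above_metrics: ModelMetrics

    @property
    def residual_stats(self) -> dict[str, tuple[float, float]]:
        """(mean, sd) of held-out residuals per combustion model."""
        return {
            "belowground": (self.below_metrics.residual_mean,
                            self.below_metrics.residual_sd),
            "aboveground": (self.above_metrics.residual_mean,
                            self.above_metrics.residual_sd),
        }


def _repeated_oof(X: np.ndarray, y: np.ndarray, params: dict, folds: int,
                  repeats: int, seed: int) -> np.ndarray:
    """Per-plot out-of-fold predictions averaged over seeded repeats.

    Every plot's prediction always comes from folds its row was excluded
    from; each repeat reshuffles the fold assignment.
    """
    preds = np.zeros((repeats, len(y)))
    seen = np.zeros((repeats, len(y)), dtype=bool)
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=(int(seed) + 9973 * r) % (2**31))
        for tr, te in kf.split(X):
            model = _make_model(params, seed + r)
            model.fit(X[tr], y[tr])
            preds[r, te] = model.predict(X[te])
            seen[r, te] = True
    if not seen.all():
        raise RuntimeError("some plots never held out — empty fold?")
    return preds.mean(axis=0)


def _metrics(y: np.ndarray, pred: np.ndarray) -> ModelMetrics:
    resid = pred - y
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_mean = float(np.nanmean(np.where(y != 0, pred / y, np.nan)))
    return ModelMetrics(
        r2=1.0 - ss_res / ss_tot if ss_tot else np.nan,
        rmse=float(np.sqrt(np.mean(resid**2))),
        relative_bias=float((pred.mean() - y.mean()) / y.mean()),
        relative_bias_ratio_mean=ratio_mean,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)),
        oof_prediction=pred,
    )


def fit_evaluate(plots: pd.DataFrame, depth_sel: Selection,
                 below_sel: Selection, above_sel: Selection,
                 folds: int = 10, repeats: int = 100, seed: int = 0,
                 depth_col: str = "burn_depth",
                 below_col: str = "belowground_cc",
                 above_col: str = "aboveground_cc") -> ModelBundle:
    """Fit and cross-validate the three models with depth chaining.

    The belowground model consumes the depth model's averaged out-of-fold
    prediction as an extra feature, so no observed depth (and no in-fold
    depth prediction) ever leaks into combustion training.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y_depth = plots[depth_col].to_numpy(float)
    X_depth = plots[depth_sel.features].to_numpy(float)
    depth_oof = _repeated_oof(X_depth, y_depth, depth_sel.params, folds,
                              repeats, seed)
    depth_metrics = _metrics(y_depth, depth_oof)

    below_features = [f for f in below_sel.features if f != DEPTH_FEATURE]
    X_below = np.column_stack(
        [plots[below_features].to_numpy(float), depth_oof])
    y_below = plots[below_col].to_numpy(float)
    below_oof = _repeated_oof(X_below, y_below, below_sel.params, folds,
                              repeats, seed + 1)
    below_metrics = _metrics(y_below, below_oof)

    X_above = plots[above_sel.features].to_numpy(float)
    y_above = plots[above_col].to_numpy(float)
    above_oof = _repeated_oof(X_above, y_above, above_sel.params, folds,
                              repeats, seed + 2)
    above_metrics = _metrics(y_above, above_oof)

    depth_model = _make_model(depth_sel.params, seed)
    depth_model.fit(X_depth, y_depth)
    below_model = _make_model(below_sel.params, seed + 1)
    below_model.fit(X_below, y_below)
    above_model = _make_model(above_sel.params, seed + 2)
    above_model.fit(X_above, y_above)

    below_sel = Selection(features=below_features + [DEPTH_FEATURE],
                          params=below_sel.params, cv_rmse=below_sel.cv_rmse,
                          rfe_path=below_sel.rfe_path,
                          search_history=below_sel.search_history)
    return ModelBundle(
        depth_model=depth_model, below_model=below_model,
        above_model=above_model, depth_selection=depth_sel,
        below_selection=below_sel, above_selection=above_sel,
        depth_metrics=depth_metrics, below_metrics=below_metrics,
        above_metrics=above_metrics)


@dataclass
class PixelPredictions:
    """Per-pixel depth and combustion predictions on the burned mask."""

    depth_cm: np.ndarray
    belowground_cc: np.ndarray
    aboveground_cc: np.ndarray
    n_floored: int


def predict_pixels(bundle: ModelBundle, rasters: dict[str, np.ndarray],
                   burned: np.ndarray) -> PixelPredictions:
    """Apply the fitted models to per-pixel predictor rasters.

    Predictions are emitted only on burned pixels; at prediction time the
    chained depth entering the belowground model is the depth model's
    direct prediction (no CV averaging exists outside evaluation).
    Negative predictions are floored at zero and counted.
    """
    burned = np.asarray(burned, dtype=bool)
    for sel in (bundle.depth_selection, bundle.below_selection,
                bundle.above_selection):
        for name in sel.features:
            if name != DEPTH_FEATURE and name not in rasters:
                raise KeyError(f"missing predictor raster: {name}")
    rr, cc = np.nonzero(burned)
    shape = burned.shape
    depth = np.full(shape, np.nan)
    below = np.full(shape, np.nan)
    above = np.full(shape, np.nan)
    n_floored = 0
    if rr.size:
        Xd = np.column_stack(
            [np.asarray(rasters[n], float)[rr, cc]
             for n in bundle.depth_selection.features])
        d = bundle.depth_model.predict(Xd).astype(float)
        cols = []
        for name in bundle.below_selection.features:
            cols.append(d if name == DEPTH_FEATURE
                        else np.asarray(rasters[name], float)[rr, cc])
        b = bundle.below_model.predict(np.column_stack(cols)).astype(float)
        Xa = np.column_stack(
            [np.asarray(rasters[n], float)[rr, cc]
             for n in bundle.above_selection.features])
        a = bundle.above_model.predict(Xa).astype(float)
        for arr in (d, b, a):
            n_floored += int((arr < 0).sum())
        depth[rr, cc] = np.clip(d, 0.0, None)
        below[rr, cc] = np.clip(b, 0.0, None)
        above[rr, cc] = np.clip(a, 0.0, None)
        if n_floored:
            logger.info("floored %d negative pixel predictions at 0", n_floored)
    return PixelPredictions(depth_cm=depth, belowground_cc=below,
                            aboveground_cc=above, n_floored=n_floored)


G_PER_PG = 1e15


def aggregate_emissions(preds: PixelPredictions, burned: np.ndarray,
                        peat_fire: np.ndarray, pixel_area: float = 900.0,
                        year: int | None = None) -> pd.DataFrame:
    """Totals and per-area means by pool (below/aboveground) and peat class.

    Total carbon = Σ cc_i · A_i (g C, also in Pg C); per-area mean =
    total / Σ A_i (g C m⁻²).
    """
    burned = np.asarray(burned, dtype=bool)
    peat_fire = np.asarray(peat_fire, dtype=bool) & burned
    rows = []
    for cls, mask in (("all", burned), ("peat", peat_fire),
                      ("nonpeat", burned & ~peat_fire)):
        area = float(mask.sum()) * pixel_area
        for pool, raster in (("belowground", preds.belowground_cc),
                             ("aboveground", preds.aboveground_cc)):
            vals = raster[mask]
            total = float(np.nansum(vals)) * pixel_area
            rows.append({
                "year": year, "class": cls, "pool": pool,
                "area_m2": area, "total_g_c": total,
                "total_pg_c": total / G_PER_PG,
                "mean_g_c_m2": total / area if area else np.nan,
            })
        vals = preds.belowground_cc[mask] + preds.aboveground_cc[mask]
        total = float(np.nansum(vals)) * pixel_area
        rows.append({
            "year": year, "class": cls, "pool": "total",
            "area_m2": area, "total_g_c": total,
            "total_pg_c": total / G_PER_PG,
            "mean_g_c_m2": total / area if area else np.nan,
        })
    return pd.DataFrame(rows)
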