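"""Gradient-boosted combustion models: selection, chaining, aggregation."""

import numpy as np
import pandas as pd
import pytest

from peatfire import emissions as em
from peatfire import synthetic


def planted_plots(n=300, n_features=12, noise_sd=0.3, seed=0):
    X, y, informative = synthetic.planted_regression(
        n=n, n_features=n_features, noise_sd=noise_sd, seed=seed)
    df = X.copy()
    df["target"] = y
    return df, informative


class TestTuneAndSelect:
    def test_budget_one_returns_single_sampled_configuration(self):
        df, _ = planted_plots()
        sel = em.tune_and_select(df, "target", list(df.columns[:-1]),
                                 budget=1, folds=3, seed=0, rfe=False)
        assert len(sel.search_history) == 1
        assert sel.params == sel.search_history[0][0]

    def test_budget_below_one_rejected(self):
        df, _ = planted_plots()
        with pytest.raises(ValueError):
            em.tune_and_select(df, "target", list(df.columns[:-1]), budget=0)

    def test_informative_features_survive_rfe(self):
        df, informative = planted_plots(n=250, n_features=10, noise_sd=0.2)
        sel = em.tune_and_select(df, "target", list(df.columns[:-1]),
                                 budget=1, folds=4, seed=0)
        assert set(informative) <= set(sel.features)

    def test_duplicate_column_collapses_to_one(self):
        df, informative = planted_plots(n=250, n_features=6, noise_sd=0.2)
        df["f00_copy"] = df["f00"]
        sel = em.tune_and_select(
            df, "target", [c for c in df.columns if c != "target"],
            budget=1, folds=4, seed=0)
        assert not {"f00", "f00_copy"} <= set(sel.features)
        assert {"f00", "f00_copy"} & set(sel.features)

    def test_hyperparameter_space_has_eight_entries(self):
        assert len(em.HYPERPARAM_SPACE) == 8

    def test_seeded_search_reproducible(self):
        df, _ = planted_plots(n=150, n_features=5)
        kwargs = dict(budget=3, folds=3, seed=9, rfe=False)
        s1 = em.tune_and_select(df, "target", list(df.columns[:-1]), **kwargs)
        s2 = em.tune_and_select(df, "target", list(df.columns[:-1]), **kwargs)
        assert s1.params == s2.params and s1.cv_rmse == s2.cv_rmse


def selection(features, params=None):
    return em.Selection(features=list(features),
                        params=params or dict(em.DEFAULT_PARAMS),
                        cv_rmse=np.nan)


class TestFitEvaluate:
    @pytest.fixture(scope="class")
    def bundle_and_plots(self):
        cfg = synthetic.SimConfig(rng_seed=13)
        plots = synthetic.simulate_field_plots(cfg, n=400)
        depth_sel = selection(synthetic.INFORMATIVE_PREDICTORS)
        below_sel = selection(list(synthetic.INFORMATIVE_PREDICTORS)
                              + [em.DEPTH_FEATURE])
        above_sel = selection(["aboveground_biomass", "tree_cover"])
        bundle = em.fit_evaluate(plots, depth_sel, below_sel, above_sel,
                                 folds=5, repeats=3, seed=4)
        return bundle, plots

    def test_noiseless_linear_target_near_perfect(self):
        # bounded covariates keep held-out folds inside the training domain,
        # so a high-capacity booster reaches the learnable limit
        rng = np.random.default_rng(3)
        n = 1000
        X = rng.uniform(-1, 1, (n, 2))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1]
        params = dict(em.DEFAULT_PARAMS, n_estimators=1000, learning_rate=0.3,
                      max_depth=8, min_child_weight=1.0, reg_lambda=0.0,
                      reg_alpha=0.0, subsample=1.0, colsample_bytree=1.0)
        pred = em._repeated_oof(X, y, params, folds=5, repeats=1, seed=0)
        assert em._metrics(y, pred).r2 >= 0.99

    def test_out_of_fold_discipline_on_pure_noise(self):
        # a memorizing model predicting its own training rows would score
        # near-perfect; held-out predictions on iid noise must not
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 3))
        y = rng.normal(size=300)
        params = dict(em.DEFAULT_PARAMS, n_estimators=400, learning_rate=0.3,
                      min_child_weight=1.0, max_depth=8)
        model = em._make_model(params, 0)
        model.fit(X, y)
        assert em._metrics(y, model.predict(X)).r2 > 0.9  # memorizes
        oof = em._repeated_oof(X, y, params, folds=5, repeats=2, seed=0)
        assert em._metrics(y, oof).r2 < 0.2  # no leakage

    def test_more_repeats_stabilize_predictions(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(0, 1.0, 200)
        params = dict(em.DEFAULT_PARAMS, n_estimators=60)
        def spread(repeats, seeds=(0, 1000)):
            preds = [em._repeated_oof(X, y, params, 4, repeats, s)
                     for s in seeds]
            return float(np.mean(np.abs(preds[0] - preds[1])))
        assert spread(8) < spread(1)

    def test_depth_feature_enters_belowground_model(self, bundle_and_plots):
        bundle, _ = bundle_and_plots
        assert em.DEPTH_FEATURE in bundle.below_selection.features
        # observed depth never appears among belowground features
        assert "burn_depth" not in bundle.below_selection.features

    def test_metrics_and_residual_stats_present(self, bundle_and_plots):
        bundle, plots = bundle_and_plots
        assert np.isfinite(bundle.depth_metrics.r2)
        mu, sd = bundle.residual_stats["belowground"]
        resid = (bundle.below_metrics.oof_prediction
                 - plots["belowground_cc"].to_numpy())
        assert mu == pytest.approx(resid.mean())
        assert sd == pytest.approx(resid.std(ddof=1))

    def test_partial_dependence_signs_match_generator(self, bundle_and_plots):
        bundle, plots = bundle_and_plots
        # raising each planted depth predictor raises predicted depth
        base = plots[list(synthetic.INFORMATIVE_PREDICTORS)].mean()
        lo = base.copy()
        hi = base.copy()
        for name in synthetic.INFORMATIVE_PREDICTORS:
            lo[name] = plots[name].quantile(0.1)
            hi[name] = plots[name].quantile(0.9)
            p_lo = bundle.depth_model.predict(
                lo.to_numpy().reshape(1, -1))[0]
            p_hi = bundle.depth_model.predict(
                hi.to_numpy().reshape(1, -1))[0]
            assert p_hi > p_lo
            lo[name] = base[name]
            hi[name] = base[name]


class TestPredictPixels:
    @pytest.fixture(scope="class")
    def bundle(self):
        cfg = synthetic.SimConfig(rng_seed=13)
        plots = synthetic.simulate_field_plots(cfg, n=300)
        return em.fit_evaluate(
            plots, selection(synthetic.INFORMATIVE_PREDICTORS),
            selection(list(synthetic.INFORMATIVE_PREDICTORS)
                      + [em.DEPTH_FEATURE]),
            selection(["aboveground_biomass", "tree_cover"]),
            folds=4, repeats=2, seed=4)

    def rasters(self, value=None, rng=None, shape=(10, 10)):
        out = {}
        for name in list(synthetic.INFORMATIVE_PREDICTORS) + [
                "aboveground_biomass"]:
            if value is not None:
                out[name] = np.full(shape, float(value))
            else:
                out[name] = rng.uniform(0, 50, shape)
        return out

    def test_unburned_pixels_get_no_prediction(self, bundle):
        burned = np.zeros((10, 10), dtype=bool)
        burned[2, 2] = True
        preds = em.predict_pixels(bundle, self.rasters(value=20.0), burned)
        assert np.isfinite(preds.depth_cm[2, 2])
        assert np.isnan(preds.depth_cm[~burned]).all()

    def test_constant_rasters_give_constant_predictions(self, bundle):
        burned = np.ones((10, 10), dtype=bool)
        preds = em.predict_pixels(bundle, self.rasters(value=25.0), burned)
        assert np.ptp(preds.belowground_cc) == 0.0
        assert np.ptp(preds.depth_cm) == 0.0

    def test_missing_raster_named_in_error(self, bundle):
        rasters = self.rasters(value=20.0)
        del rasters["tree_cover"]
        with pytest.raises(KeyError, match="tree_cover"):
            em.predict_pixels(bundle, rasters, np.ones((10, 10), bool))


class TestAggregate:
    def preds(self, below, above, shape=(5, 5)):
        return em.PixelPredictions(
            depth_cm=np.full(shape, 10.0),
            belowground_cc=np.full(shape, float(below)),
            aboveground_cc=np.full(shape, float(above)),
            n_floored=0)

    def test_single_pixel_arithmetic(self):
        burned = np.zeros((5, 5), dtype=bool)
        burned[0, 0] = True
        tab = em.aggregate_emissions(self.preds(3000, 0), burned,
                                     np.zeros((5, 5), bool))
        below = tab[(tab["class"] == "all") & (tab["pool"] == "belowground")]
        assert below["total_g_c"].iloc[0] == pytest.approx(2.7e6)

    def test_belowground_share_of_total(self):
        # per-area means 3010 (below) and 417 (above) -> 88% belowground
        burned = np.ones((5, 5), dtype=bool)
        tab = em.aggregate_emissions(self.preds(3010, 417), burned,
                                     np.zeros((5, 5), bool))
        sub = tab[tab["class"] == "all"].set_index("pool")
        share = (sub.loc["belowground", "mean_g_c_m2"]
                 / sub.loc["total", "mean_g_c_m2"])
        assert share == pytest.approx(0.878, abs=0.005)
        assert sub.loc["total", "mean_g_c_m2"] == pytest.approx(3427.0)

    def test_zero_burned_pixels_zero_totals(self):
        burned = np.zeros((5, 5), dtype=bool)
        tab = em.aggregate_emissions(self.preds(3000, 400), burned,
                                     np.zeros((5, 5), bool))
        assert (tab["total_g_c"] == 0).all()

    def test_peat_class_partition(self):
        burned = np.ones((4, 4), dtype=bool)
        peat = np.zeros((4, 4), dtype=bool)
        peat[:2] = True
        tab = em.aggregate_emissions(self.preds(1000, 100, (4, 4)), burned, peat)
        tot = tab.set_index(["class", "pool"])["total_g_c"]
        assert tot["peat", "total"] + tot["nonpeat", "total"] == \
            pytest.approx(tot["all", "total"])
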