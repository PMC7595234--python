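"""Boosted-regression-tree fitting, selection, influence, PD, and ensembles."""

import numpy as np
import pandas as pd
import pytest

from droughtsense import synthetic
from droughtsense.attribution import (
    BoostedRegressionTrees,
    BrtParams,
    EnsembleResult,
    cv_statistics,
    ensemble_runs,
    fit_boosted_trees,
    prune_predictors,
)


@pytest.fixture(scope="module")
def step_table(request):
    """Response is a deterministic step function of one predictor."""
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, 400)
    return pd.DataFrame(
        {"x": x, "noise1": rng.normal(size=400), "y": np.where(x < 0, 5.0, 10.0)}
    )


@pytest.fixture(scope="module")
def signal_table():
    return synthetic.make_attribution_dataset(n_pixels=2500, target_r2=0.6, seed=9)


FAST = dict(learning_rate=0.1, max_trees=300, step_size=50, cv_folds=4)


class TestFitBoostedTrees:
    def test_single_stump_reproduces_group_means(self, step_table):
        est = BoostedRegressionTrees(
            tree_complexity=1, bag_fraction=1.0, learning_rate=1.0,
            max_trees=1, select_trees=False, random_state=0,
        )
        est.fit(step_table[["x"]], step_table["y"])
        pred = est.predict(step_table[["x"]])
        assert np.allclose(np.sort(np.unique(np.round(pred, 9))), [5.0, 10.0])

    def test_boosting_additivity_identity(self, signal_table):
        """pred_n = pred_{n-1} + learning_rate * tree_n output at every stage."""
        preds = ["elev", "soil_bd", "cti"]
        est = BoostedRegressionTrees(
            learning_rate=0.1, max_trees=25, bag_fraction=1.0,
            select_trees=False, random_state=3,
        )
        est.fit(signal_table[preds], signal_table["s_response"])
        X20 = signal_table[preds].head(20)
        staged = list(est.staged_predict(X20))
        Xa = est._encode_X(X20, fit=False)
        for n in range(1, len(staged)):
            tree_out = est.model_.estimators_[n, 0].predict(Xa)
            np.testing.assert_allclose(
                staged[n], staged[n - 1] + 0.1 * tree_out, rtol=1e-10, atol=1e-10
            )

    def test_training_mse_nonincreasing_without_bagging(self, signal_table):
        preds = ["elev", "soil_bd"]
        est = BoostedRegressionTrees(
            learning_rate=0.1, max_trees=60, bag_fraction=1.0,
            select_trees=False, random_state=1,
        )
        est.fit(signal_table[preds], signal_table["s_response"])
        y = signal_table["s_response"].to_numpy()
        mses = [np.mean((y - p) ** 2) for p in est.staged_predict(signal_table[preds])]
        assert all(a >= b - 1e-9 for a, b in zip(mses, mses[1:]))

    def test_constant_response_error(self, step_table):
        with pytest.raises(ValueError, match="constant response"):
            fit_boosted_trees(
                step_table.assign(y=1.0), ["x"], "y", BrtParams(**FAST)
            )

    def test_missing_response_error(self, step_table):
        bad = step_table.copy()
        bad.loc[bad.index[0], "y"] = np.nan
        with pytest.raises(ValueError, match="missing response"):
            fit_boosted_trees(bad, ["x"], "y", BrtParams(**FAST))

    def test_deterministic_under_seed(self, signal_table):
        preds = ["elev", "soil_bd", "cti"]
        kw = dict(learning_rate=0.2, max_trees=40, select_trees=False, random_state=7)
        a = BoostedRegressionTrees(**kw).fit(signal_table[preds], signal_table["s_response"])
        b = BoostedRegressionTrees(**kw).fit(signal_table[preds], signal_table["s_response"])
        np.testing.assert_array_equal(
            a.predict(signal_table[preds].head(50)), b.predict(signal_table[preds].head(50))
        )

    def test_sklearn_params_round_trip(self):
        est = BoostedRegressionTrees(learning_rate=0.07)
        params = est.get_params()
        assert params["learning_rate"] == 0.07
        est2 = BoostedRegressionTrees().set_params(**params)
        assert est2.get_params() == params


class TestStepSelection:
    def test_trace_bookkeeping(self, signal_table):
        preds = ["elev", "soil_bd", "deficit"]
        est = BoostedRegressionTrees(
            learning_rate=0.2, max_trees=500, step_size=25, cv_folds=4,
            patience=3, random_state=2,
        )
        est.fit(signal_table[preds], signal_table["s_response"])
        trace = est.cv_deviance_trace_
        best = trace["cv_deviance"].idxmin()
        assert est.n_trees_selected_ == trace.loc[best, "n_trees"]
        if trace["n_trees"].iloc[-1] < 500:  # stopped by patience
            assert len(trace) == best + 1 + 3

    def test_strong_signal_beats_null_deviance(self, signal_table):
        preds = ["elev", "soil_bd", "deficit", "aet"]
        stats = cv_statistics(signal_table, preds, "s_response", BrtParams(seed=4, **FAST))
        assert stats["pct_deviance_explained"] > 40
        assert stats["cv_correlation"] > 0.6

    def test_permutation_null_cv_correlation(self, signal_table):
        """With a permuted response, CV correlation centers on zero."""
        rng = np.random.default_rng(5)
        sub = signal_table.head(400).copy()
        rs = []
        for s in range(6):
            sub["y_perm"] = rng.permutation(sub["s_response"].to_numpy())
            stats = cv_statistics(
                sub, ["elev", "soil_bd", "cti"], "y_perm",
                BrtParams(seed=s, learning_rate=0.1, max_trees=150, step_size=50, cv_folds=4),
            )
            r = stats["cv_correlation"]
            rs.append(0.0 if np.isnan(r) else r)
        assert abs(np.mean(rs)) < 0.1

    def test_deviance_explained_bounded(self, signal_table):
        stats = cv_statistics(
            signal_table, ["elev", "soil_bd"], "s_response", BrtParams(seed=1, **FAST)
        )
        assert stats["pct_deviance_explained"] <= 100


class TestRelativeInfluence:
    def test_single_variable_model(self, step_table):
        fit = fit_boosted_trees(
            step_table, ["x", "noise1"], "y",
            BrtParams(seed=0, learning_rate=0.5, max_trees=100, step_size=25, cv_folds=4),
        )
        assert fit.relative_influence_["x"] > 99.0
        assert fit.relative_influence_.sum() == pytest.approx(100.0, abs=1e-6)

    def test_sums_to_100(self, signal_table):
        preds = ["elev", "soil_bd", "deficit", "aet", "cti", "hli"]
        fit = fit_boosted_trees(signal_table, preds, "s_response", BrtParams(seed=6, **FAST))
        assert fit.relative_influence_.sum() == pytest.approx(100.0, abs=1e-6)

    def test_true_drivers_dominate(self, signal_table):
        preds = ["elev", "soil_bd", "deficit", "aet", "soil_awc", "wtd", "cti", "hli", "shade_dens"]
        fit = fit_boosted_trees(signal_table, preds, "s_response", BrtParams(seed=8, **FAST))
        ri = fit.relative_influence_.sort_values(ascending=False)
        assert set(ri.index[:2]) == {"elev", "soil_bd"}


class TestPartialDependence:
    def test_stump_closed_form(self, step_table):
        est = BoostedRegressionTrees(
            tree_complexity=1, bag_fraction=1.0, learning_rate=1.0,
            max_trees=1, select_trees=False, random_state=0,
        )
        est.fit(step_table[["x"]], step_table["y"])
        pd_curve = est.partial_dependence(step_table[["x"]], "x", grid_size=11, trim=(0, 100))
        assert pd_curve["yhat"].iloc[0] == pytest.approx(5.0)
        assert pd_curve["yhat"].iloc[-1] == pytest.approx(10.0)

    def test_irrelevant_predictor_constant_curve(self, step_table):
        fit = fit_boosted_trees(
            step_table, ["x", "noise1"], "y",
            BrtParams(seed=0, learning_rate=0.5, max_trees=50, step_size=25, cv_folds=4),
        )
        curve = fit.partial_dependence(step_table[["x", "noise1"]], "noise1", grid_size=15)
        assert curve["yhat"].std() < 0.05 * step_table["y"].std()

    def test_monotone_truth_recovered(self, signal_table):
        """PD for elevation rises monotonically when the truth does."""
        from scipy.stats import spearmanr

        preds = ["elev", "soil_bd", "deficit", "aet", "cti"]
        fit = fit_boosted_trees(signal_table, preds, "s_response", BrtParams(seed=3, **FAST))
        curve = fit.partial_dependence(signal_table[preds], "elev", grid_size=40)
        rho = spearmanr(curve["value"], curve["yhat"])[0]
        assert rho >= 0.9
        lo, hi = curve.attrs["trim"]
        assert lo == pytest.approx(np.percentile(signal_table["elev"], 5))
        assert hi == pytest.approx(np.percentile(signal_table["elev"], 95))


@pytest.fixture(scope="module")
def small_ensemble(signal_table):
    preds = ["elev", "soil_bd", "deficit", "aet", "cti", "hli", "shade_dens"]
    return ensemble_runs(
        signal_table, preds, "s_response",
        BrtParams(seed=None, **FAST), n_runs=4, sample_size=800,
        pd_grid_size=15, seed=10,
    )


class TestEnsemble:
    def test_shapes_and_influence_rows(self, small_ensemble):
        ens = small_ensemble
        assert ens.n_runs == 4
        assert len(ens.relative_influence) == 4
        np.testing.assert_allclose(ens.relative_influence.sum(axis=1), 100.0, atol=1e-6)
        assert set(ens.pd_curves) == set(ens.predictors)
        for curve in ens.pd_curves.values():
            assert {"value", "mean", "q25", "q75"} <= set(curve.columns)

    def test_degenerate_single_run(self, signal_table):
        preds = ["elev", "soil_bd"]
        ens = ensemble_runs(
            signal_table, preds, "s_response",
            BrtParams(seed=None, **FAST), n_runs=1, sample_size=600,
            pd_grid_size=8, seed=3,
        )
        summ = ens.influence_summary()
        assert np.allclose(summ["median"], summ["mean"])
        assert np.allclose(summ["q25"], summ["q75"])

    def test_sample_size_capped_with_warning(self, signal_table, caplog):
        preds = ["elev", "soil_bd"]
        with caplog.at_level("WARNING"):
            ens = ensemble_runs(
                signal_table, preds, "s_response",
                BrtParams(seed=None, **FAST), n_runs=1, sample_size=10**6,
                pd_grid_size=5, seed=3,
            )
        assert ens.sample_size == len(signal_table)

    def test_sampling_variability_shrinks_with_sample_size(self, signal_table):
        preds = ["elev", "soil_bd", "cti"]

        def top_iqr(n):
            ens = ensemble_runs(
                signal_table, preds, "s_response",
                BrtParams(seed=None, learning_rate=0.2, max_trees=150, step_size=50, cv_folds=3),
                n_runs=6, sample_size=n, pd_grid_size=5, seed=12,
            )
            ri = ens.relative_influence["elev"]
            return ri.quantile(0.75) - ri.quantile(0.25)

        assert top_iqr(2000) < top_iqr(300)


class TestPrune:
    def _ens(self, med: dict) -> EnsembleResult:
        ri = pd.DataFrame([med, med])
        return EnsembleResult(ri, pd.DataFrame(), {}, 2, 100, list(med))

    def test_threshold_rule(self):
        kept, dropped = prune_predictors(self._ens({"A": 60, "B": 30, "C": 6, "D": 4}), 5)
        assert kept == ["A", "B", "C"]
        assert dropped == ["D"]

    def test_zero_threshold_keeps_all(self):
        kept, dropped = prune_predictors(self._ens({"A": 60, "B": 40}), 0)
        assert dropped == []

    def test_all_below_threshold_error(self):
        with pytest.raises(ValueError, match="all predictors"):
            prune_predictors(self._ens({"A": 1, "B": 2}), 5)
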