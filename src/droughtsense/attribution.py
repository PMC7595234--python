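"""Boosted-regression-tree attribution of drought-sensitivity patterns.

Fits stagewise gradient-boosted regression trees of S' on landscape
predictors, with the stepwise cross-validated tree-count selection used in
ecological BRT practice: trees are added in fixed-size steps while tenfold
cross-validated squared-error deviance is monitored, and the ensemble size
minimizing CV deviance is selected (with a patience stop). Reported model
products are

* relative influence — percent of total split-wise squared-error reduction
  attributable to each predictor (sums to 100);
* partial dependence — model-predicted S' as a function of one predictor
  averaged over a reference sample of the others, interpreted between the
  5th and 95th predictor percentiles;
* fit statistics — cross-validated Pearson correlation and percent deviance
  explained, pooled over held-out folds.

The full protocol repeats the fit over bootstrapped runs (default 20 random
samples of 10,000 pixels), averages the products, and prunes predictors
whose median relative influence falls below a threshold.

The boosting engine is scikit-learn's ``GradientBoostingRegressor``; the
selection, influence/partial-dependence reporting, ensemble and pruning
protocol live here. ``tree_complexity`` (the number of splits per tree)
maps to ``max_leaf_nodes = tree_complexity + 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "BrtParams",
    "BoostedRegressionTrees",
    "EnsembleResult",
    "fit_boosted_trees",
    "cv_statistics",
    "partial_dependence",
    "ensemble_runs",
    "prune_predictors",
]


@dataclass(frozen=True)
class BrtParams:
    """Hyperparameters of the BRT protocol.

    tree_complexity is the number of splits per tree (interaction depth);
    bag_fraction the stochastic subsample per stage; step_size the number
    of trees added per CV monitoring step; patience the number of steps
    without CV improvement before stopping.
    """

    tree_complexity: int = 5
    bag_fraction: float = 0.5
    learning_rate: float = 0.005
    step_size: int = 50
    max_trees: int = 10_000
    cv_folds: int = 10
    patience: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class BoostedRegressionTrees(RegressorMixin, BaseEstimator):
    """Gradient-boosted regression trees with stepwise CV tree selection.

    Parameters mirror :class:`BrtParams`. With ``select_trees=True`` the
    ensemble size is chosen by k-fold cross-validation: trees are added
    ``step_size`` at a time, held-out squared-error deviance is recorded
    per step, and the size minimizing mean CV deviance is kept (stopping
    once the minimum has not improved for ``patience`` steps). With
    ``select_trees=False`` exactly ``max_trees`` trees are fitted and no CV
    statistics are computed.

    Attributes (after fit)
    ----------------------
    model_ : fitted ``GradientBoostingRegressor``
    n_trees_selected_ : int
    cv_deviance_trace_ : DataFrame with columns n_trees, cv_deviance
    cv_correlation_ : float — Pearson r of pooled out-of-fold predictions
        against the response at the selected size
    pct_deviance_explained_ : float — 100 * (1 - pooled out-of-fold
        squared-error deviance / null deviance about the training mean)
    relative_influence_ : Series (percent per predictor, sums to 100)
    feature_names_in_ : ndarray of predictor names
    """

    def __init__(
        self,
        tree_complexity: int = 5,
        bag_fraction: float = 0.5,
        learning_rate: float = 0.005,
        step_size: int = 50,
        max_trees: int = 10_000,
        cv_folds: int = 10,
        patience: int = 5,
        select_trees: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.tree_complexity = tree_complexity
        self.bag_fraction = bag_fraction
        self.learning_rate = learning_rate
        self.step_size = step_size
        self.max_trees = max_trees
        self.cv_folds = cv_folds
        self.patience = patience
        self.select_trees = select_trees
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _new_gbm(self, n_estimators: int, random_state: int | None) -> GradientBoostingRegressor:
        return GradientBoostingRegressor(
            loss="squared_error",
            learning_rate=self.learning_rate,
            n_estimators=n_estimators,
            subsample=self.bag_fraction,
            max_leaf_nodes=self.tree_complexity + 1,
            max_depth=None,
            warm_start=True,
            random_state=random_state,
        )

    def _encode_X(self, X: pd.DataFrame | np.ndarray, fit: bool) -> np.ndarray:
        """Ordinal-encode non-numeric columns; remember the level maps."""
        if not isinstance(X, pd.DataFrame):
            arr = np.asarray(X, dtype=float)
            if fit:
                self.feature_names_in_ = np.array([f"x{i}" for i in range(arr.shape[1])])
                self._categories: dict[str, pd.Index] = {}
            return arr
        if fit:
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            self._categories = {}
        arr = np.empty((len(X), X.shape[1]), dtype=float)
        for j, col in enumerate(self.feature_names_in_):
            vals = X[col]
            if pd.api.types.is_numeric_dtype(vals):
                arr[:, j] = vals.to_numpy(dtype=float)
            else:
                if fit:
                    levels = pd.Index(sorted(vals.unique()))
                    self._categories[col] = levels
                levels = self._categories[col]
                codes = levels.get_indexer(vals)
                if (codes < 0).any():
                    # unseen level: map to the modal training level
                    warnings.warn(
                        f"unseen category in {col!r}; mapped to majority level",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    codes = np.where(codes < 0, 0, codes)
                arr[:, j] = codes
        return arr

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y):  # noqa: D102 — class docstring describes the procedure
        Xa = self._encode_X(X, fit=True)
        y = np.asarray(y, dtype=float)
        if Xa.ndim != 2 or len(y) != Xa.shape[0]:
            raise ValueError("X must be 2-D with one response value per row")
        if np.isnan(y).any():
            raise ValueError("missing values in the response")
        if np.ptp(y) == 0:
            raise ValueError("constant response: nothing to model")
        self.n_features_in_ = Xa.shape[1]
        rs = self.random_state

        if self.select_trees:
            self._step_select(Xa, y, rs)
        else:
            self.n_trees_selected_ = self.max_trees
            self.cv_deviance_trace_ = pd.DataFrame(columns=["n_trees", "cv_deviance"])
            self.cv_correlation_ = np.nan
            self.pct_deviance_explained_ = np.nan

        final = self._new_gbm(self.n_trees_selected_, rs)
        final.fit(Xa, y)
        self.model_ = final
        imp = final.feature_importances_
        total = imp.sum()
        if total <= 0:
            warnings.warn(
                "zero total split reduction; relative influence set uniform",
                RuntimeWarning,
                stacklevel=2,
            )
            ri = np.full(self.n_features_in_, 100.0 / self.n_features_in_)
        else:
            ri = 100.0 * imp / total
        self.relative_influence_ = pd.Series(ri, index=self.feature_names_in_)
        return self

    def _step_select(self, Xa: np.ndarray, y: np.ndarray, rs: int | None) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 for tree selection")
        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=rs)
        folds = list(kf.split(Xa))
        if any(len(te) < 2 for _, te in folds):
            raise ValueError("cross-validation fold with fewer than 2 rows")
        models = [
            self._new_gbm(0, None if rs is None else rs + 1 + i)
            for i in range(self.cv_folds)
        ]
        oof_by_step: list[np.ndarray] = []
        trace: list[tuple[int, float]] = []
        best_step, best_dev = -1, np.inf
        step = 0
        while True:
            step += 1
            n_trees = min(step * self.step_size, self.max_trees)
            oof = np.empty_like(y)
            for m, (tr, te) in zip(models, folds):
                m.set_params(n_estimators=n_trees)
                m.fit(Xa[tr], y[tr])
                oof[te] = m.predict(Xa[te])
            dev = float(np.mean((y - oof) ** 2))
            trace.append((n_trees, dev))
            oof_by_step.append(oof)
            if dev < best_dev:
                best_dev, best_step = dev, step - 1
            if n_trees >= self.max_trees:
                if best_step == step - 1:
                    warnings.warn(
                        "CV deviance minimum at max_trees; consider a smaller "
                        "learning_rate or larger max_trees",
                        RuntimeWarning,
                        stacklevel=3,
                    )
                break
            if step - 1 - best_step >= self.patience:
                break
        self.cv_deviance_trace_ = pd.DataFrame(trace, columns=["n_trees", "cv_deviance"])
        self.n_trees_selected_ = int(self.cv_deviance_trace_["n_trees"].iloc[best_step])
        best_oof = oof_by_step[best_step]
        self.cv_correlation_ = float(pearsonr(best_oof, y)[0])
        null_dev = float(np.mean((y - y.mean()) ** 2))
        self.pct_deviance_explained_ = 100.0 * (1.0 - best_dev / null_dev)

    def predict(self, X):  # noqa: D102
        check_is_fitted(self, "model_")
        return self.model_.predict(self._encode_X(X, fit=False))

    def staged_predict(self, X):
        """Predictions after each boosting stage (additivity diagnostics)."""
        check_is_fitted(self, "model_")
        return self.model_.staged_predict(self._encode_X(X, fit=False))

    def partial_dependence(
        self,
        X_ref: pd.DataFrame,
        predictor: str,
        grid_size: int = 100,
        trim: tuple[float, float] = (5.0, 95.0),
        ref_cap: int = 1000,
        random_state: int | None = 0,
    ) -> pd.DataFrame:
        """Partial-dependence curve for one predictor.

        For each grid value v spanning the trimmed percentile range of the
        predictor, the model prediction is averaged over a reference sample
        (at most ``ref_cap`` rows of ``X_ref``) with the predictor forced
        to v. Categorical predictors get one row per observed level.

        Returns a DataFrame with columns ``value`` and ``yhat``; the
        percentile trim bounds are stored in ``df.attrs['trim']``.
        """
        check_is_fitted(self, "model_")
        ref = X_ref
        if len(ref) > ref_cap:
            ref = ref.sample(n=ref_cap, random_state=random_state)
        if predictor in getattr(self, "_categories", {}):
            levels = self._categories[predictor]
            rows = []
            for lev in levels:
                mod = ref.copy()
                mod[predictor] = lev
                rows.append((lev, float(self.predict(mod).mean())))
            out = pd.DataFrame(rows, columns=["value", "yhat"])
            out.attrs["trim"] = None
            return out
        col = X_ref[predictor].to_numpy(dtype=float)
        lo, hi = np.percentile(col, trim)
        grid = np.linspace(lo, hi, grid_size)
        yhat = np.empty(grid_size)
        for i, v in enumerate(grid):
            mod = ref.copy()
            mod[predictor] = v
            yhat[i] = float(self.predict(mod).mean())
        out = pd.DataFrame({"value": grid, "yhat": yhat})
        out.attrs["trim"] = (float(lo), float(hi))
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def _estimator(params: BrtParams, select_trees: bool = True) -> BoostedRegressionTrees:
    return BoostedRegressionTrees(
        tree_complexity=params.tree_complexity,
        bag_fraction=params.bag_fraction,
        learning_rate=params.learning_rate,
        step_size=params.step_size,
        max_trees=params.max_trees,
        cv_folds=params.cv_folds,
        patience=params.patience,
        select_trees=select_trees,
        random_state=params.seed,
    )


def fit_boosted_trees(
    table: pd.DataFrame,
    predictors: list[str],
    response: str,
    params: BrtParams | None = None,
    select_trees: bool = True,
    min_rows: int = 100,
) -> BoostedRegressionTrees:
    """Fit the BRT model on a merged sensitivity + covariate table."""
    params = params or BrtParams()
    if len(table) < min_rows:
        raise ValueError(f"need >= {min_rows} rows to fit, got {len(table)}")
    if table[response].isna().any():
        raise ValueError("missing response values; filter invalid pixels first")
    est = _estimator(params, select_trees)
    return est.fit(table[predictors], table[response])


def cv_statistics(
    table: pd.DataFrame,
    predictors: list[str],
    response: str,
    params: BrtParams | None = None,
) -> dict[str, float]:
    """Cross-validated correlation and percent deviance explained."""
    fit = fit_boosted_trees(table, predictors, response, params)
    return {
        "cv_correlation": fit.cv_correlation_,
        "pct_deviance_explained": fit.pct_deviance_explained_,
        "n_trees_selected": fit.n_trees_selected_,
    }


def partial_dependence(
    fit: BoostedRegressionTrees,
    X_ref: pd.DataFrame,
    predictor: str,
    grid_size: int = 100,
    **kwargs,
) -> pd.DataFrame:
    """Module-level wrapper over :meth:`BoostedRegressionTrees.partial_dependence`."""
    return fit.partial_dependence(X_ref, predictor, grid_size=grid_size, **kwargs)


# ---------------------------------------------------------------------------
# ensemble protocol


@dataclass
class EnsembleResult:
    """Summaries over bootstrapped BRT runs.

    relative_influence: one row per successful run, one column per
    predictor. fit_stats: per-run cv_correlation / pct_deviance_explained /
    n_trees. pd_curves: predictor -> DataFrame(value, mean, q25, q75) on a
    grid shared across runs.
    """

    relative_influence: pd.DataFrame
    fit_stats: pd.DataFrame
    pd_curves: dict[str, pd.DataFrame]
    n_runs: int
    sample_size: int
    predictors: list[str] = field(default_factory=list)

    def influence_summary(self) -> pd.DataFrame:
        ri = self.relative_influence
        return pd.DataFrame(
            {
                "median": ri.median(),
                "mean": ri.mean(),
                "q25": ri.quantile(0.25),
                "q75": ri.quantile(0.75),
            }
        ).sort_values("median", ascending=False)

    def fit_summary(self) -> pd.DataFrame:
        fs = self.fit_stats
        return pd.DataFrame(
            {"median": fs.median(), "q25": fs.quantile(0.25), "q75": fs.quantile(0.75)}
        )


def ensemble_runs(
    table: pd.DataFrame,
    predictors: list[str],
    response: str,
    params: BrtParams | None = None,
    n_runs: int = 20,
    sample_size: int = 10_000,
    replace: bool = False,
    pd_grid_size: int = 50,
    pd_predictors: list[str] | None = None,
    seed: int = 0,
) -> EnsembleResult:
    """Bootstrapped BRT ensemble: repeated fits on random pixel samples.

    Each run draws ``sample_size`` rows (without replacement by default)
    with a run-specific seed, fits and selects a model, and records
    relative influence, fit statistics, and partial-dependence curves
    evaluated on a grid common to all runs (the trimmed percentile range of
    each predictor over the full table). A failing run is skipped with a
    log message; fewer than half succeeding is an error.
    """
    params = params or BrtParams()
    rng = np.random.default_rng(seed)
    if sample_size > len(table) and not replace:
        logger.warning(
            "sample_size %d > %d rows; lowered to table size", sample_size, len(table)
        )
        sample_size = len(table)
    pd_predictors = pd_predictors if pd_predictors is not None else list(predictors)
    numeric_pd = [
        p for p in pd_predictors if pd.api.types.is_numeric_dtype(table[p])
    ]
    grids = {
        p: np.linspace(*np.percentile(table[p].to_numpy(dtype=float), [5, 95]), pd_grid_size)
        for p in numeric_pd
    }

    ri_rows, stat_rows = [], []
    pd_acc: dict[str, list[np.ndarray]] = {p: [] for p in numeric_pd}
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    for r in range(n_runs):
        run_rng = np.random.default_rng(run_seeds[r])
        idx = run_rng.choice(len(table), size=sample_size, replace=replace)
        sample = table.iloc[idx]
        try:
            p_run = _dc_replace(params, seed=int(run_seeds[r] % (2**31 - 1)))
            fit = fit_boosted_trees(sample, predictors, response, p_run)
        except Exception as exc:  # noqa: BLE001 — any run failure is skipped
            logger.warning("ensemble run %d failed: %s", r, exc)
            continue
        ri_rows.append(fit.relative_influence_)
        stat_rows.append(
            {
                "cv_correlation": fit.cv_correlation_,
                "pct_deviance_explained": fit.pct_deviance_explained_,
                "n_trees": fit.n_trees_selected_,
            }
        )
        ref = sample[predictors]
        for p in numeric_pd:
            grid = grids[p]
            curve = _pd_on_grid(fit, ref, p, grid, random_state=int(run_seeds[r] % 2**31))
            pd_acc[p].append(curve)
    if len(ri_rows) < max(1, n_runs // 2):
        raise RuntimeError(f"only {len(ri_rows)} of {n_runs} ensemble runs succeeded")

    ri = pd.DataFrame(ri_rows).reset_index(drop=True)
    stats = pd.DataFrame(stat_rows)
    curves = {}
    for p in numeric_pd:
        arr = np.vstack(pd_acc[p])
        curves[p] = pd.DataFrame(
            {
                "value": grids[p],
                "mean": arr.mean(axis=0),
                "q25": np.quantile(arr, 0.25, axis=0),
                "q75": np.quantile(arr, 0.75, axis=0),
            }
        )
    return EnsembleResult(ri, stats, curves, len(ri_rows), sample_size, list(predictors))


def _pd_on_grid(
    fit: BoostedRegressionTrees,
    ref: pd.DataFrame,
    predictor: str,
    grid: np.ndarray,
    ref_cap: int = 1000,
    random_state: int = 0,
) -> np.ndarray:
    if len(ref) > ref_cap:
        ref = ref.sample(n=ref_cap, random_state=random_state)
    out = np.empty(grid.size)
    mod = ref.copy()
    for i, v in enumerate(grid):
        mod[predictor] = v
        out[i] = float(fit.predict(mod).mean())
    return out


def prune_predictors(
    ensemble: EnsembleResult, threshold_pct: float = 5.0
) -> tuple[list[str], list[str]]:
    """Drop predictors with median relative influence below the threshold.

    Returns (kept, dropped), preserving the input predictor order. All
    predictors falling below the threshold is an error.
    """
    med = ensemble.relative_influence.median()
    kept = [p for p in ensemble.predictors if med[p] >= threshold_pct]
    dropped = [p for p in ensemble.predictors if med[p] < threshold_pct]
    if not kept:
        raise ValueError("all predictors fall below the influence threshold")
    return kept, dropped
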