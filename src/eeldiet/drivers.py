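"""Random-forest driver analysis of proximate composition vs larval outcomes.

For each period and trait, a random-forest regression relates the estimated
proximate composition of every tested diet (crude protein, crude lipid,
crude ash, crude carbohydrate, nucleic acids — % of dry matter) to its
standardized outcome.  Hyperparameters are tuned by grid search; both the
five-fold cross-validated R² and the out-of-bag R² are reported, with CV R²
as the default selection criterion.  Predictions are attributed to the
nutrient features via exact Shapley values, and per-feature dependence is
summarized as binned mean attributions with bootstrap confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._treeshap import shap_dependence_table, tree_shap_values

DRIVER_FEATURES = (
    "crude_protein",
    "crude_lipid",
    "crude_ash",
    "crude_carbohydrate",
    "nucleic_acids",
)

DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [3, 5, None],
    "min_samples_leaf": [1, 3, 5],
}


class DriverError(ValueError):
    pass


def _grid_points(grid: dict) -> list[dict]:
    pts = [{}]
    for key, values in grid.items():
        pts = [{**p, key: v} for p in pts for v in values]
    return pts


def _r2(y, yhat) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(((y - yhat) ** 2).sum()) / sst


class DriverModel:
    """RF regression of one standardized trait on proximate composition.

    Parameters
    ----------
    X : DataFrame or array, shape (n, 5)
        Estimated proximate composition per diet × trial row (% DM), in
        :data:`DRIVER_FEATURES` order when unlabeled.
    y : array-like
        Standardized outcome (z-scores) per row.
    grid : dict, optional
        Hyperparameter grid; defaults to :data:`DEFAULT_GRID`.
    """

    def __init__(self, X, y, grid: dict | None = None):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.feature_names = list(DRIVER_FEATURES[: self.X.shape[1]])
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise DriverError("X must be (n, d) with one y per row")
        if not np.isfinite(self.y).all() or self.y.std() == 0:
            raise DriverError("target must be finite with non-zero variance")
        self.grid = grid if grid is not None else DEFAULT_GRID
        if not self.grid:
            raise DriverError("empty hyperparameter grid")

    def _score_point(self, params: dict, folds: int, seed: int) -> dict:
        n = len(self.y)
        kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
        yhat = np.empty(n)
        for tr, te in kf.split(self.X):
            rf = RandomForestRegressor(random_state=seed, **params)
            rf.fit(self.X[tr], self.y[tr])
            yhat[te] = rf.predict(self.X[te])
        cv_r2 = _r2(self.y, yhat)
        rf_full = RandomForestRegressor(
            random_state=seed, oob_score=True, bootstrap=True, **params
        )
        rf_full.fit(self.X, self.y)
        return {"params": params, "cv_r2": cv_r2,
                "oob_r2": float(rf_full.oob_score_), "model": rf_full}

    def fit(self, seed: int = 0, folds: int = 5, criterion: str = "cv"
            ) -> "DriverResults":
        """Grid-search the forest and return results for the best point.

        ``criterion`` selects on ``"cv"`` (five-fold CV R², default) or
        ``"oob"`` (out-of-bag R²).
        """
        if criterion not in ("cv", "oob"):
            raise DriverError(f"unknown selection criterion {criterion!r}")
        scored = [self._score_point(p, folds, seed) for p in _grid_points(self.grid)]
        key = "cv_r2" if criterion == "cv" else "oob_r2"
        best = max(range(len(scored)), key=lambda i: scored[i][key])
        report = pd.DataFrame(
            [{**s["params"], "cv_r2": s["cv_r2"], "oob_r2": s["oob_r2"]}
             for s in scored]
        )
        return DriverResults(self, scored[best]["model"], scored[best]["params"],
                             report, seed=seed, criterion=criterion,
                             cv_r2=scored[best]["cv_r2"])


class DriverResults:
    """Fitted driver forest: importances, Shapley attributions, dependence."""

    def __init__(self, model, forest, params, grid_report, seed, criterion,
                 cv_r2):
        self.model = model
        self.forest = forest
        self.params = params
        self.grid_report = grid_report
        self.seed = seed
        self.criterion = criterion
        self.cv_r2 = float(cv_r2)
        self._shap_cache: tuple[np.ndarray, float] | None = None

    @property
    def oob_r2(self) -> float:
        return float(self.forest.oob_score_)

    def importance_pct(self) -> pd.Series:
        """Impurity-decrease importances normalized to sum 100."""
        imp = self.forest.feature_importances_
        return pd.Series(100.0 * imp / imp.sum(), index=self.model.feature_names)

    def shap_values(self) -> tuple[np.ndarray, float]:
        """Exact per-sample Shapley attributions and the base value."""
        if self._shap_cache is None:
            self._shap_cache = tree_shap_values(self.forest, self.model.X)
        return self._shap_cache

    def mean_abs_shap_pct(self) -> pd.Series:
        phi, _ = self.shap_values()
        m = np.abs(phi).mean(axis=0)
        return pd.Series(100.0 * m / m.sum(), index=self.model.feature_names)

    def dependence_table(self, feature: str, n_bins: int = 10,
                         n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
        """Binned (feature value, mean attribution, bootstrap CI) rows."""
        if feature not in self.model.feature_names:
            raise DriverError(f"unknown feature {feature!r}")
        phi, _ = self.shap_values()
        idx = self.model.feature_names.index(feature)
        rec = shap_dependence_table(self.model.X, phi, idx, n_bins=n_bins,
                                    n_boot=n_boot, seed=seed)
        return pd.DataFrame(rec)

    def summary(self) -> str:
        imp = self.importance_pct().sort_values(ascending=False)
        lines = [
            "Random-forest driver analysis",
            "=" * 60,
            f"Observations:  {len(self.model.y)}",
            f"Selected grid point ({self.criterion} R2): {self.params}",
            f"CV R2:  {self.cv_r2:.3f}    OOB R2: {self.oob_r2:.3f}",
            "",
            "Variable importance (%):",
            imp.to_string(float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: v for k, v in self.params.items()},
            "cv_r2": self.cv_r2,
            "oob_r2": self.oob_r2,
            "seed": self.seed,
            "criterion": self.criterion,
            "importance_pct": self.importance_pct().to_dict(),
            "mean_abs_shap_pct": self.mean_abs_shap_pct().to_dict(),
        }


def fit_rf_cv(X, y, grid: dict | None = None, folds: int = 5, seed: int = 0,
              criterion: str = "cv") -> DriverResults:
    """Convenience wrapper: grid-searched driver forest in one call."""
    return DriverModel(X, y, grid=grid).fit(seed=seed, folds=folds,
                                            criterion=criterion)
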