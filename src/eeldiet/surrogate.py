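"""Gaussian-process surrogates of standardized larval outcomes.

One surrogate is fitted per trait (survival z, TL z) and developmental
period, regressing on the seven normalized ingredient proportions.  Both
explanatory and objective variables are auto-scaled (zero mean, unit
variance) using training statistics; explanatory variables with zero
variance are excluded.  The kernel is selected from a candidate set — all
combinations of {squared exponential, Matérn ν = 3/2} × {isotropic,
per-dimension lengthscales} × {with, without an additive linear (dot
product) term}, each with a white-noise term — by 10-fold cross-validation
maximizing predictive R².

The interface follows the model/results idiom: build a
:class:`GPSurrogate` from (X, y), call :meth:`~GPSurrogate.fit`, and work
with the returned :class:`GPSurrogateResults` (predict with uncertainty,
cross-validation report, summary table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    Matern,
    WhiteKernel,
)
from sklearn.model_selection import KFold

from .formulations import SimplexPoint


class SurrogateError(ValueError):
    pass


@dataclass(frozen=True)
class ScalerStats:
    """Training mean/SD per retained variable plus the retained-column mask."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    mask: np.ndarray  # boolean over original X columns; False = zero variance

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.mask] - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        return y_scaled * self.y_sd + self.y_mean


def autoscale(
    X: np.ndarray, y: np.ndarray, stats: ScalerStats | None = None
) -> tuple[np.ndarray, np.ndarray, ScalerStats]:
    """Center/scale X and y; fit mode computes stats, apply mode reuses them.

    Zero-variance X columns are dropped in fit mode and recorded in the
    returned mask.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if stats is None:
        sd_all = X.std(axis=0, ddof=0)
        mask = sd_all > 0
        if not mask.any():
            raise SurrogateError("every explanatory variable has zero variance")
        y_sd = float(y.std(ddof=0))
        if y_sd == 0:
            raise SurrogateError("objective variable has zero variance")
        stats = ScalerStats(
            x_mean=X[:, mask].mean(axis=0),
            x_sd=sd_all[mask],
            y_mean=float(y.mean()),
            y_sd=y_sd,
            mask=mask,
        )
    return stats.transform_x(X), stats.transform_y(y), stats


@dataclass(frozen=True)
class KernelSpec:
    """Covariance structure: family, lengthscale mode, optional linear term.

    A white-noise term is always included.
    """

    family: str = "rbf"  # "rbf" (squared exponential) or "matern" (nu = 1.5)
    ard: bool = False  # per-dimension lengthscales when True
    linear: bool = False  # additive DotProduct term

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "matern"):
            raise SurrogateError(f"unknown kernel family {self.family!r}")

    def build(self, n_dims: int):
        ls = np.ones(n_dims) if self.ard else 1.0
        bounds = (1e-3, 1e3)
        if self.family == "rbf":
            stationary = RBF(length_scale=ls, length_scale_bounds=bounds)
        else:
            stationary = Matern(length_scale=ls, length_scale_bounds=bounds, nu=1.5)
        kernel = ConstantKernel(1.0, bounds) * stationary + WhiteKernel(
            1.0, noise_level_bounds=(1e-10, 1e3)
        )
        if self.linear:
            kernel = kernel + ConstantKernel(1.0, bounds) * DotProduct(
                sigma_0=1.0, sigma_0_bounds=bounds
            )
        return kernel

    @property
    def complexity(self) -> tuple[int, int]:
        """Tie-break key: (number of terms, per-dimension lengthscales)."""
        return (2 + self.linear, int(self.ard))

    @property
    def name(self) -> str:
        parts = ["RBF" if self.family == "rbf" else "Matern(nu=1.5)"]
        parts[0] += "[ard]" if self.ard else ""
        parts.append("White")
        if self.linear:
            parts.append("DotProduct")
        return " + ".join(parts)


def default_kernel_candidates() -> list[KernelSpec]:
    """The eight-candidate closure of the kernel forms used for selection."""
    return [
        KernelSpec(family=f, ard=a, linear=l)
        for f in ("rbf", "matern")
        for a in (False, True)
        for l in (False, True)
    ]


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """R² (1 − SSE/SST), RMSE and MAE; R² is NaN when y has zero variance."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise SurrogateError("regression_metrics needs equal-length arrays, n >= 2")
    resid = y - yhat
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else np.nan
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
    }


def _fit_single(
    X_scaled: np.ndarray, y_scaled: np.ndarray, spec: KernelSpec,
    seed: int, n_restarts: int
) -> GaussianProcessRegressor:
    gpr = GaussianProcessRegressor(
        kernel=spec.build(X_scaled.shape[1]),
        alpha=1e-10,
        n_restarts_optimizer=n_restarts,
        normalize_y=False,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            gpr.fit(X_scaled, y_scaled)
        except (LinAlgError, np.linalg.LinAlgError, ValueError) as exc:
            raise SurrogateError(f"GP optimizer failed for kernel {spec.name}: {exc}")
    return gpr


class GPSurrogate:
    """GP regression model of one standardized trait on simplex coordinates.

    Parameters
    ----------
    X : array-like, shape (n, 7)
        Normalized ingredient proportions (rows sum to one).
    y : array-like, shape (n,)
        Standardized outcome (z-scores).
    candidates : list of KernelSpec, optional
        Kernels considered during cross-validation selection; defaults to
        :func:`default_kernel_candidates`.
    n_restarts : int
        Restarts of the marginal-likelihood optimizer (default 5).
    """

    def __init__(self, X, y, candidates: list[KernelSpec] | None = None,
                 n_restarts: int = 5):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise SurrogateError("X must be (n, d) with one y per row")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise SurrogateError("non-finite values in training data")
        if self.X.shape[0] < 5:
            raise SurrogateError("need at least 5 observations to fit a surrogate")
        self.candidates = candidates or default_kernel_candidates()
        self.n_restarts = n_restarts

    def _cv_metrics(self, spec: KernelSpec, folds: int, seed: int) -> dict[str, float]:
        """Pooled out-of-fold predictions -> predictive R2/RMSE/MAE."""
        n = len(self.y)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        yhat = np.empty(n)
        for train_idx, test_idx in kf.split(self.X):
            Xs, ys, stats = autoscale(self.X[train_idx], self.y[train_idx])
            gpr = _fit_single(Xs, ys, spec, seed, self.n_restarts)
            pred = gpr.predict(stats.transform_x(self.X[test_idx]))
            yhat[test_idx] = stats.inverse_y(pred)
        m = regression_metrics(self.y, yhat)
        return {f"cv_{k}": v for k, v in m.items()}

    def fit(self, seed: int = 0, folds: int = 10, select: bool = True
            ) -> "GPSurrogateResults":
        """Select a kernel by k-fold CV (when >1 candidate) and fit on all data."""
        n = len(self.y)
        folds = min(folds, n)
        rows = []
        specs = self.candidates if select else self.candidates[:1]
        if n < folds:
            raise SurrogateError(f"n = {n} < folds = {folds}")
        Xs_all, ys_all, stats = autoscale(self.X, self.y)
        for spec in specs:
            gpr = _fit_single(Xs_all, ys_all, spec, seed, self.n_restarts)
            train = regression_metrics(
                self.y, stats.inverse_y(gpr.predict(Xs_all))
            )
            row = {"kernel": spec.name, "spec": spec}
            row.update({f"train_{k}": v for k, v in train.items()})
            if len(specs) > 1 or select:
                row.update(self._cv_metrics(spec, folds, seed))
            rows.append((row, gpr))
        report = pd.DataFrame([r for r, _ in rows])
        if "cv_r2" in report.columns:
            best_r2 = report["cv_r2"].max()
            tied = [
                i for i, (r, _) in enumerate(rows)
                if r["cv_r2"] >= best_r2 - 1e-9
            ]
            best_i = min(tied, key=lambda i: (rows[i][0]["spec"].complexity, i))
        else:
            best_i = 0
        best_row, best_gpr = rows[best_i]
        return GPSurrogateResults(
            model=self,
            kernel_spec=best_row["spec"],
            gpr=best_gpr,
            scaler=stats,
            cv_report=report.drop(columns=["spec"]),
            seed=seed,
            folds=folds,
        )


class GPSurrogateResults:
    """Fitted surrogate: kernel, scaler statistics, CV report, predictions."""

    def __init__(self, model, kernel_spec, gpr, scaler, cv_report, seed, folds):
        self.model = model
        self.kernel_spec = kernel_spec
        self.gpr = gpr
        self.scaler = scaler
        self.cv_report = cv_report
        self.seed = seed
        self.folds = folds

    @property
    def kernel_(self) -> str:
        return str(self.gpr.kernel_)

    def predict(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and SD on the standardized-outcome (z) scale."""
        if isinstance(points, SimplexPoint):
            X = points.proportions[None, :]
        else:
            X = np.atleast_2d(np.asarray(points, dtype=float))
        if X.shape[1] != self.scaler.mask.size:
            raise SurrogateError(
                f"expected {self.scaler.mask.size} coordinates, got {X.shape[1]}"
            )
        mu_s, sd_s = self.gpr.predict(self.scaler.transform_x(X), return_std=True)
        mu = self.scaler.inverse_y(mu_s)
        sd = sd_s * self.scaler.y_sd
        return mu, np.maximum(sd, 0.0)

    def to_dict(self) -> dict:
        """JSON-serializable model metadata."""
        return {
            "kernel_spec": {
                "family": self.kernel_spec.family,
                "ard": self.kernel_spec.ard,
                "linear": self.kernel_spec.linear,
            },
            "kernel_fitted": self.kernel_,
            "scaler": {
                "x_mean": self.scaler.x_mean.tolist(),
                "x_sd": self.scaler.x_sd.tolist(),
                "y_mean": self.scaler.y_mean,
                "y_sd": self.scaler.y_sd,
                "mask": self.scaler.mask.tolist(),
            },
            "seed": self.seed,
            "folds": self.folds,
            "n_obs": len(self.model.y),
        }

    def summary(self) -> str:
        lines = [
            "Gaussian-process surrogate",
            "=" * 60,
            f"Observations:      {len(self.model.y)}",
            f"Retained features: {int(self.scaler.mask.sum())} of {self.scaler.mask.size}",
            f"Selected kernel:   {self.kernel_spec.name}",
            f"Fitted kernel:     {self.kernel_}",
            f"CV folds / seed:   {self.folds} / {self.seed}",
            "",
            self.cv_report.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def fit_gpr(X, y, spec: KernelSpec, seed: int = 0, n_restarts: int = 5
            ) -> GPSurrogateResults:
    """Fit a single-kernel surrogate (no cross-validation selection)."""
    return GPSurrogate(X, y, candidates=[spec], n_restarts=n_restarts).fit(
        seed=seed, select=False
    )


def select_kernel_cv(
    X, y, candidates: list[KernelSpec] | None = None,
    folds: int = 10, seed: int = 0, n_restarts: int = 5,
) -> tuple[KernelSpec, pd.DataFrame]:
    """Cross-validated kernel selection; returns (best spec, CV report)."""
    res = GPSurrogate(X, y, candidates=candidates, n_restarts=n_restarts).fit(
        seed=seed, folds=folds
    )
    return res.kernel_spec, res.cv_report


def predict_with_uncertainty(results: GPSurrogateResults, point) -> tuple[float, float]:
    """Predictive mean and SD at one simplex point, in z units."""
    mu, sd = results.predict(point)
    return float(mu[0]), float(sd[0])
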