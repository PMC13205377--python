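"""Body-weight regression from biometric features, with R2 / MAPE scoring.

Two model families predict scale body weight from the four per-video median
features (dorsal length, abdominal width, height, volume): ordinary least
squares, and a random forest whose feature-subset size per split is tuned
by seeded 5-fold cross-validation minimizing RMSE.  Agreement between
predicted and scale BW is scored by the coefficient of determination

    R2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

and the mean absolute percentage error

    MAPE = (100 / n) * sum |y_i - yhat_i| / y_i .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "RegressionModel",
    "FitMetrics",
    "RegressionError",
    "fit_ols",
    "fit_rf",
    "volumetric_model",
    "evaluate",
]


class RegressionError(ValueError):
    """Invalid regression inputs (rank deficiency, missing values, ...)."""


@dataclass
class FitMetrics:
    r2: float
    mape: float
    n: int


@dataclass
class RegressionModel:
    """A BW estimator: OLS coefficients, a tuned random forest, or a
    model-based volumetric calibration curve.

    The ``volumetric`` kind predicts BW by inverting a monotone
    volume-versus-BW calibration (``grid_bw``, ``grid_vol``) by
    interpolation; it takes the single feature ``volume`` and involves no
    statistical fitting — it encodes the constant-clearance assumption of
    depth-based volumetrics.
    """

    kind: str
    feature_names: list[str]
    intercept: float = 0.0
    coef: np.ndarray | None = None
    estimator: RandomForestRegressor | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)
    grid_bw: np.ndarray | None = None
    grid_vol: np.ndarray | None = None

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = self._design(features)
        if self.kind == "ols":
            return self.intercept + X @ self.coef
        if self.kind == "volumetric":
            return np.interp(X[:, 0], self.grid_vol, self.grid_bw)
        return self.estimator.predict(X)

    def _design(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise RegressionError(f"missing feature column(s) {missing}")
            X = features[self.feature_names].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(features, dtype=np.float64)
            if X.shape[1] != len(self.feature_names):
                raise RegressionError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        return X


def _check_xy(features, bw):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(bw, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise RegressionError("feature rows and BW length differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise RegressionError("missing values in features or BW")
    return X, y, names


def fit_ols(features, bw) -> RegressionModel:
    """Ordinary least squares BW regression (intercept included).

    Raises :class:`RegressionError` naming the collinear columns when the
    design is rank deficient (detected by QR with column pivoting).
    """
    X, y, names = _check_xy(features, bw)
    n, p = X.shape
    if n <= p + 1:
        raise RegressionError(f"need n > {p + 1} observations, got {n}")
    A = np.column_stack([np.ones(n), X])
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p + 1:
        bad = sorted(piv[rank:])
        cols = ["intercept" if j == 0 else names[j - 1] for j in bad]
        raise RegressionError(f"rank-deficient design; collinear column(s): {cols}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return RegressionModel(
        kind="ols", feature_names=names, intercept=float(beta[0]), coef=beta[1:]
    )


def fit_rf(
    features,
    bw,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    min_samples_leaf: int = 5,
) -> RegressionModel:
    """Random-forest BW regression with CV-tuned feature-subset size.

    Only ``max_features`` (the number of candidate features per split) is
    tuned, over 1..p, by ``folds``-fold cross-validation minimizing RMSE;
    tree count and minimum node size stay at their defaults.  Fully
    deterministic given ``seed``; the CV table is kept on the model.
    """
    X, y, names = _check_xy(features, bw)
    n, p = X.shape
    if n < folds:
        raise RegressionError(f"need at least {folds} observations for {folds}-fold CV")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    records = []
    for mf in range(1, p + 1):
        sse, cnt = 0.0, 0
        for tr, te in splits:
            est = RandomForestRegressor(
                n_estimators=n_estimators,
                min_samples_leaf=min_samples_leaf,
                max_features=mf,
                random_state=seed,
                n_jobs=1,
            )
            est.fit(X[tr], y[tr])
            resid = y[te] - est.predict(X[te])
            sse += float(resid @ resid)
            cnt += len(te)
        records.append({"max_features": mf, "cv_rmse": np.sqrt(sse / cnt)})
    cv = pd.DataFrame(records)
    best = int(cv.loc[cv["cv_rmse"].idxmin(), "max_features"])
    est = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        max_features=best,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return RegressionModel(kind="rf", feature_names=names, estimator=est, cv_table=cv)


def volumetric_model(grid_bw: np.ndarray, grid_vol: np.ndarray) -> RegressionModel:
    """Model-based BW estimator from a monotone volume(BW) calibration curve."""
    grid_bw = np.asarray(grid_bw, dtype=np.float64)
    grid_vol = np.asarray(grid_vol, dtype=np.float64)
    if grid_bw.size != grid_vol.size or grid_bw.size < 2:
        raise RegressionError("calibration grids must be equal length >= 2")
    if np.any(np.diff(grid_vol) <= 0):
        raise RegressionError("volume calibration must be strictly increasing")
    return RegressionModel(
        kind="volumetric", feature_names=["volume"], grid_bw=grid_bw, grid_vol=grid_vol
    )


def evaluate(y, yhat) -> FitMetrics:
    """Score predictions: R2 = 1 - SSres/SStot, MAPE = 100/n * sum|y-yhat|/y."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size != yhat.size:
        raise RegressionError("y and yhat lengths differ")
    if y.size < 2:
        raise RegressionError("need at least 2 observations")
    if np.any(y == 0.0):
        raise RegressionError("MAPE undefined: some y_i is zero")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise RegressionError("R2 undefined: y is constant")
    ssres = float(np.sum((y - yhat) ** 2))
    mape = float(100.0 / y.size * np.sum(np.abs(y - yhat) / np.abs(y)))
    return FitMetrics(r2=1.0 - ssres / sstot, mape=mape, n=int(y.size))
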