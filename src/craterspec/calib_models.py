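"""Calibration models and evaluation metrics for Cd quantification.

Provides the univariate calibration curve ``y = a x + b``, multiple linear
regression (MLR), partial least squares regression (PLSR), the least-squares
support vector machine (LSSVM) and random-forest (RF) regression, plus the
shared evaluation metrics: determination coefficient R^2, root-mean-square
error (RMSEC / RMSEP, ug/g) and, for the univariate curve, the limit of
detection and quantification (3 sigma / slope and 10 sigma / slope).

PLSR and RF are delegated to scikit-learn.  The LSSVM is the canonical
equality-constrained kernel ridge dual: solve

    [ 0    1^T          ] [ b     ]   [ 0 ]
    [ 1    K + I/gamma  ] [ alpha ] = [ y ]

with RBF (or linear) kernel K; prediction is ``f(x) = sum_i alpha_i k(x, x_i) + b``.
Kernel methods are scale-sensitive, so the LSSVM standardizes its inputs
internally and records the transform; all other models consume raw units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from scipy.spatial.distance import pdist, squareform, cdist

from .core_data import SpectrumSet
from .errors import ModelError

__all__ = [
    "r2",
    "rmse",
    "EvaluationReport",
    "CurveModel",
    "MLRModel",
    "PLSRModel",
    "LSSVMModel",
    "RFModel",
    "fit_curve",
    "fit_mlr",
    "fit_plsr",
    "fit_lssvm",
    "fit_rf",
    "lod_loq_from_sigma",
    "lod_loq",
    "evaluate",
    "pca_scores",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Determination coefficient ``1 - SS_res / SS_tot``."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ModelError(f"r2 needs two equal-length vectors with n >= 2, got {y.shape}/{yhat.shape}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ModelError("references are constant; R^2 undefined")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error between references and predictions."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ModelError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class EvaluationReport:
    """Calibration/prediction metrics for one fitted model (concentrations in ug/g)."""

    Rc2: float
    RMSEC: float
    Rp2: float
    RMSEP: float
    LOD: float | None = None
    LOQ: float | None = None

    def as_dict(self) -> dict:
        return {
            "Rc2": self.Rc2, "RMSEC": self.RMSEC,
            "Rp2": self.Rp2, "RMSEP": self.RMSEP,
            "LOD": self.LOD, "LOQ": self.LOQ,
        }


# ---------------------------------------------------------------------------
# Feature plumbing
# ---------------------------------------------------------------------------

def _as_matrix(features, feature_names: Sequence[str] | None) -> np.ndarray:
    """Coerce a DataFrame / array to the column order a model was fitted with."""
    if isinstance(features, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in features.columns]
            if missing:
                raise ModelError(f"feature columns missing: {missing}")
            features = features[list(feature_names)]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is not None and X.shape[1] != len(feature_names):
            raise ModelError(
                f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
            )
    if not np.all(np.isfinite(X)):
        raise ModelError("features contain non-finite values")
    return X


def _names_of(features) -> list[str]:
    if isinstance(features, pd.DataFrame):
        return [str(c) for c in features.columns]
    X = np.asarray(features)
    k = 1 if X.ndim == 1 else X.shape[1]
    return [f"x{i}" for i in range(k)]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class CurveModel:
    """Univariate calibration curve: concentration predicted as ``a * intensity + b``.

    ``inverse_slope`` / ``inverse_sigma`` hold the classical calibration-curve
    fit in intensity space (intensity regressed on concentration), used for
    the 3-sigma/slope detection limit.
    """

    kind = "curve"
    slope: float
    intercept: float
    feature_name: str
    inverse_slope: float
    inverse_sigma: float
    residual_sigma_conc: float

    @property
    def feature_names(self) -> list[str]:
        return [self.feature_name]

    def predict(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        return self.slope * X[:, 0] + self.intercept


@dataclass
class MLRModel:
    """Ordinary least squares on named features (raw units)."""

    kind = "mlr"
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]

    def predict(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        return X @ self.coefficients + self.intercept


@dataclass
class PLSRModel:
    """Partial least squares regression (scikit-learn NIPALS, unscaled)."""

    kind = "plsr"
    estimator: PLSRegression
    n_components: int
    feature_names: list[str]
    cv_rmse_path: list[float] = field(default_factory=list)

    def predict(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        return self.estimator.predict(X).ravel()


@dataclass
class LSSVMModel:
    """Least-squares SVM regression (dual saddle-point solution)."""

    kind = "lssvm"
    alpha: np.ndarray
    bias: float
    gamma: float
    sigma: float | None  # RBF width in standardized space; None for linear kernel
    kernel: str
    X_train: np.ndarray  # standardized support points (all training samples)
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_names: list[str]
    seed: int = 0

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "rbf":
            d2 = cdist(A, B, "sqeuclidean")
            return np.exp(-d2 / (2.0 * self.sigma**2))
        if self.kernel == "linear":
            return A @ B.T
        raise ModelError(f"unknown kernel {self.kernel!r}")

    def predict(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        Xs = (X - self.x_mean) / self.x_scale
        return self._kernel(Xs, self.X_train) @ self.alpha + self.bias


@dataclass
class RFModel:
    """Random-forest regression (seeded scikit-learn ensemble)."""

    kind = "rf"
    estimator: RandomForestRegressor
    feature_names: list[str]
    seed: int = 0

    def predict(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        return self.estimator.predict(X)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _ols_1d(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple regression of y on x: (slope, intercept, residual sigma).

    Residual sigma uses n - 2 degrees of freedom.
    """
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ModelError("predictor has zero variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sigma = math.sqrt(float(resid @ resid) / (n - 2)) if n > 2 else 0.0
    return slope, intercept, sigma


def fit_curve(x, y) -> CurveModel:
    """Fit the univariate calibration curve; prediction maps intensity to ug/g."""
    X = _as_matrix(x, None)
    if X.shape[1] != 1:
        raise ModelError("calibration curve takes exactly one intensity variable")
    name = _names_of(x)[0]
    xv = X[:, 0]
    y = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ModelError(f"curve fit needs n >= 3, got {xv.size}")
    slope, intercept, sigma_c = _ols_1d(xv, y)
    inv_slope, _, inv_sigma = _ols_1d(y, xv)  # classical intensity-vs-concentration line
    return CurveModel(
        slope=slope, intercept=intercept, feature_name=name,
        inverse_slope=inv_slope, inverse_sigma=inv_sigma,
        residual_sigma_conc=sigma_c,
    )


def fit_mlr(features, y) -> MLRModel:
    """OLS with intercept over named features."""
    X = _as_matrix(features, None)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ModelError(f"MLR needs n > k (n={n}, k={k})")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise ModelError("MLR design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MLRModel(coefficients=beta[1:], intercept=float(beta[0]), feature_names=_names_of(features))


def fit_plsr(
    features, y,
    n_components: int | None = None,
    cv: int = 10,
    seed: int = 0,
    max_components: int = 10,
) -> PLSRModel:
    """PLSR with the component count fixed or chosen by K-fold CV-RMSE."""
    X = _as_matrix(features, None)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rank = min(n - 1, p)
    path: list[float] = []
    if n_components is None:
        if cv < 2 or cv > n:
            raise ModelError(f"cv folds must be in [2, n={n}], got {cv}")
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        min_train = min(len(tr) for tr, _ in folds.split(X))
        upper = min(max_components, min_train - 1, p)
        for ncomp in range(1, upper + 1):
            sq = np.empty(n)
            for train, test in folds.split(X):
                m = PLSRegression(n_components=ncomp, scale=False)
                m.fit(X[train], y[train])
                sq[test] = (m.predict(X[test]).ravel() - y[test]) ** 2
            path.append(float(np.sqrt(sq.mean())))
        n_components = int(np.argmin(path)) + 1
    if not (1 <= n_components <= rank):
        raise ModelError(f"n_components must be in [1, rank={rank}], got {n_components}")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X, y)
    return PLSRModel(estimator=est, n_components=n_components,
                     feature_names=_names_of(features), cv_rmse_path=path)


def _lssvm_solve(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[np.ndarray, float]:
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular LSSVM system: {exc}") from exc
    return sol[1:], float(sol[0])


def fit_lssvm(
    features, y,
    gamma: float | None = None,
    sigma: float | None = None,
    kernel: str = "rbf",
    cv: int = 5,
    seed: int = 0,
) -> LSSVMModel:
    """Fit an LSSVM; hyperparameters not given are chosen by seeded CV grid search.

    Grid: regularization ``gamma`` in 10^0..10^6; RBF width ``sigma`` in
    {0.1, 1, 10} x median pairwise distance of the standardized inputs.
    """
    X = _as_matrix(features, None)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale[x_scale == 0.0] = 1.0
    Xs = (X - x_mean) / x_scale

    if kernel == "linear":
        sigmas = [None]
    elif sigma is not None:
        sigmas = [float(sigma)]
    else:
        med = float(np.median(pdist(Xs))) if n > 1 else 1.0
        med = med if med > 0 else 1.0
        sigmas = [0.1 * med, 1.0 * med, 10.0 * med]
    gammas = [float(gamma)] if gamma is not None else [10.0**k for k in range(0, 7)]

    def kernel_matrix(A: np.ndarray, B: np.ndarray, sig) -> np.ndarray:
        if kernel == "rbf":
            return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sig**2))
        if kernel == "linear":
            return A @ B.T
        raise ModelError(f"unknown kernel {kernel!r}")

    if len(gammas) > 1 or len(sigmas) > 1:
        if cv < 2 or cv > n:
            raise ModelError(f"cv folds must be in [2, n={n}], got {cv}")
        folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(Xs))
        best = (np.inf, gammas[0], sigmas[0])
        for g in gammas:
            for s in sigmas:
                sq = np.empty(n)
                for train, test in folds:
                    K = kernel_matrix(Xs[train], Xs[train], s)
                    a, b = _lssvm_solve(K, y[train], g)
                    pred = kernel_matrix(Xs[test], Xs[train], s) @ a + b
                    sq[test] = (pred - y[test]) ** 2
                score = float(np.sqrt(sq.mean()))
                if score < best[0]:
                    best = (score, g, s)
        _, g_best, s_best = best
    else:
        g_best, s_best = gammas[0], sigmas[0]

    K = kernel_matrix(Xs, Xs, s_best)
    a, b = _lssvm_solve(K, y, g_best)
    return LSSVMModel(
        alpha=a, bias=b, gamma=g_best,
        sigma=None if s_best is None else float(s_best),
        kernel=kernel, X_train=Xs, x_mean=x_mean, x_scale=x_scale,
        feature_names=_names_of(features), seed=seed,
    )


def fit_rf(features, y, n_trees: int = 500, seed: int = 0) -> RFModel:
    """Seeded random forest; one third of the features tried per split."""
    X = _as_matrix(features, None)
    y = np.asarray(y, dtype=float)
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1.0 / 3.0, 1.0 / X.shape[1]),
        random_state=seed,
    )
    est.fit(X, y)
    return RFModel(estimator=est, feature_names=_names_of(features), seed=seed)


# ---------------------------------------------------------------------------
# Detection limits
# ---------------------------------------------------------------------------

def lod_loq_from_sigma(slope: float, sigma: float) -> tuple[float, float]:
    """``(3 sigma / slope, 10 sigma / slope)``; the slope must be positive."""
    if slope <= 0:
        raise ModelError(f"detection limit requires a positive calibration slope, got {slope}")
    if sigma < 0:
        raise ModelError(f"sigma must be >= 0, got {sigma}")
    return 3.0 * sigma / slope, 10.0 * sigma / slope


def lod_loq(model: CurveModel, sigma_space: str = "intensity") -> tuple[float, float]:
    """Detection and quantification limits of a fitted calibration curve (ug/g).

    ``intensity`` (default): sigma is the residual standard deviation of the
    classical intensity-vs-concentration line and the slope its
    intensity-per-concentration gradient.  ``concentration``: sigma is the
    residual sd of predicted concentrations, already in ug/g (slope 1); this
    alternative convention is equivalent up to the curve's correlation factor.
    """
    if getattr(model, "kind", None) != "curve":
        raise ModelError("LOD/LOQ is defined only for univariate curve models")
    if sigma_space == "intensity":
        return lod_loq_from_sigma(model.inverse_slope, model.inverse_sigma)
    if sigma_space == "concentration":
        if model.slope <= 0:
            raise ModelError("detection limit requires a positive calibration slope")
        return 3.0 * model.residual_sigma_conc, 10.0 * model.residual_sigma_conc
    raise ModelError(f"unknown sigma_space {sigma_space!r}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model, cal: tuple, pred: tuple) -> EvaluationReport:
    """Fill an EvaluationReport from calibration and prediction (features, y) pairs.

    LOD/LOQ are reported for univariate curve models only.
    """
    Fc, yc = cal
    Fp, yp = pred
    yc = np.asarray(yc, dtype=float)
    yp = np.asarray(yp, dtype=float)
    yhat_c = model.predict(Fc)
    yhat_p = model.predict(Fp)
    lod = loq = None
    if getattr(model, "kind", None) == "curve":
        lod, loq = lod_loq(model)
    return EvaluationReport(
        Rc2=r2(yc, yhat_c), RMSEC=rmse(yc, yhat_c),
        Rp2=r2(yp, yhat_p), RMSEP=rmse(yp, yhat_p),
        LOD=lod, LOQ=loq,
    )


def pca_scores(ss: SpectrumSet, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA scores of a SpectrumSet and the explained-variance fractions."""
    if not (1 <= k <= min(ss.n, ss.p)):
        raise ModelError(f"k must be in [1, min(n, p)={min(ss.n, ss.p)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(ss.X)
    return scores, pca.explained_variance_ratio_
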