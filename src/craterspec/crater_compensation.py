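"""Crater-morphology compensation by backward stepwise multiple linear regression.

The twelve candidate predictors are the nine crater morphology parameters and
the three Cd emission-line intensities.  Starting from the full ordinary
least squares model, the variable whose coefficient has the highest two-sided
t-test p-value above ``alpha`` is removed, the model is refitted, and the loop
repeats until every surviving coefficient is significant (or one variable is
left).  The full p-value trajectory is recorded so the elimination path can be
inspected; p-values of surviving variables are *not* monotone along the path —
removing a collinear companion can raise or lower them — and no correction for
that is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CRATER_PARAM_NAMES, CraterProfile, ReferenceValues
from .errors import ModelError

__all__ = ["StepwiseResult", "ols_pvalues", "stepwise_backward", "summarize_craters"]


@dataclass
class StepwiseResult:
    """Outcome of a backward elimination run."""

    retained: list[str]
    elimination_order: list[tuple[str, int]]  # (variable, iteration at which it was dropped)
    p_table: pd.DataFrame  # rows = variables, columns = iteration 1..T, NaN after elimination
    coefficients: dict[str, float]
    intercept: float
    alpha: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.retained if c not in features.columns]
        if missing:
            raise ModelError(f"features missing retained columns {missing}")
        X = features[self.retained].to_numpy(dtype=float)
        beta = np.array([self.coefficients[c] for c in self.retained])
        return X @ beta + self.intercept


def ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS with intercept: returns (coefficients, intercept, two-sided t-test p-values).

    p-values use ``t = beta / SE(beta)`` with ``n - k - 1`` degrees of freedom;
    the intercept is estimated but not tested.
    """
    n, k = X.shape
    if n <= k + 1:
        raise ModelError(f"need n > k + 1 observations (n={n}, k={k})")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise ModelError("design matrix is rank deficient (collinear variables)")
    XtX_inv = np.linalg.inv(A.T @ A)
    beta = XtX_inv @ (A.T @ y)
    resid = y - A @ beta
    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t[1:]), dof)
    return beta[1:], float(beta[0]), pvals


def stepwise_backward(
    features: pd.DataFrame,
    refs: ReferenceValues | np.ndarray,
    alpha: float = 0.05,
) -> StepwiseResult:
    """Backward-eliminate predictors until all coefficient p-values are <= alpha.

    ``features`` is an ``n x k`` named matrix (mixed units are fine — t-test
    p-values are invariant to per-column rescaling).  Exactly one variable, the
    one with the highest p-value (provided it exceeds ``alpha``), is removed
    per iteration.  Elimination stops when all survivors are significant or a
    single variable remains.
    """
    y = refs.values if isinstance(refs, ReferenceValues) else np.asarray(refs, dtype=float)
    if len(features) != y.size:
        raise ModelError(f"{len(features)} feature rows but {y.size} references")
    names = [str(c) for c in features.columns]
    Xfull = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xfull)):
        raise ModelError("features contain non-finite values")

    surviving = list(names)
    p_columns: list[pd.Series] = []
    eliminated: list[tuple[str, int]] = []
    iteration = 0
    while True:
        iteration += 1
        cols = [names.index(c) for c in surviving]
        beta, intercept, pvals = ols_pvalues(Xfull[:, cols], y)
        p_columns.append(pd.Series(pvals, index=surviving, name=iteration))
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha or len(surviving) == 1:
            break
        eliminated.append((surviving[worst], iteration))
        del surviving[worst]

    p_table = pd.concat(p_columns, axis=1).reindex(names)
    return StepwiseResult(
        retained=list(surviving),
        elimination_order=eliminated,
        p_table=p_table,
        coefficients={c: float(b) for c, b in zip(surviving, beta)},
        intercept=intercept,
        alpha=alpha,
    )


def summarize_craters(craters: list[CraterProfile]) -> pd.DataFrame:
    """Min / max / mean / RSD% per crater parameter (the morphology-dispersion table).

    RSD is the relative standard deviation, ``100 * sample sd / mean``, the
    statistic used to judge how strongly the matrix perturbs ablation.
    """
    if len(craters) < 2:
        raise ModelError("need at least 2 craters to summarize dispersion")
    M = np.vstack([c.as_array() for c in craters])
    mean = M.mean(axis=0)
    if np.any(mean == 0):
        raise ModelError("zero mean crater parameter; RSD undefined")
    sd = M.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "min": M.min(axis=0),
            "max": M.max(axis=0),
            "mean": mean,
            "rsd_percent": 100.0 * sd / mean,
        },
        index=list(CRATER_PARAM_NAMES),
    )
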