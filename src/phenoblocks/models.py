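"""Regression comparison of raw-trait vs composite-phenotype predictors.

Two linear models of the oxygen-saturation change are fitted: Model 1 uses
the 27 other raw trait changes, Model 2 the 13 non-SpO2 latent-variable
scores.  Fit quality is compared by AIC, BIC, 10-fold cross-validated RMSE
and leave-one-out RMSE, with a paired one-sided Wilcoxon signed-rank test
on the fold-wise (or observation-wise) mean squared errors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr

__all__ = [
    "RegressionFit",
    "ModelComparison",
    "fit_ols",
    "fit_model1",
    "fit_model2",
    "information_criteria",
    "cross_validate",
    "compare_models",
    "compare_model_fits",
]


@dataclass
class RegressionFit:
    """OLS fit summary with Gaussian-ML information criteria.

    Predictors are standardized before fitting, so coefficients are in
    response units per predictor SD.
    """

    coefficients: pd.Series
    intercept: float
    rss: float
    n: int
    p_predictors: int
    aic: float
    bic: float
    rmse_in: float
    dropped: list[str] = field(default_factory=list)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns via pivoted QR."""
    if X.shape[1] == 0:
        return X, names, []
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    return X[:, keep], [names[i] for i in keep], dropped


def fit_ols(X: pd.DataFrame, y: pd.Series) -> RegressionFit:
    """OLS of ``y`` on standardized ``X`` with an intercept.

    Rank-deficient predictor sets have their aliased columns dropped with a
    warning.  AIC/BIC use the Gaussian-ML convention (see
    :func:`information_criteria`).
    """
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p})")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant predictor(s): {list(X.columns[sd == 0])}")
    Z = ((X - mu) / sd).values
    Z, names, dropped = _drop_aliased(Z, list(X.columns))
    if dropped:
        warnings.warn(f"dropped aliased predictor(s): {dropped}", UserWarning, stacklevel=2)
    A = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(A, y.values, rcond=None)
    resid = y.values - A @ beta
    rss = float(resid @ resid)
    tss = float(((y.values - y.values.mean()) ** 2).sum())
    if rss < 1e-12 * max(tss, 1e-300):  # numerically exact interpolation
        rss = 0.0
    p_eff = Z.shape[1]
    if rss > 0:
        aic, bic = _ic(rss, n, p_eff)
    else:  # exact interpolation: criteria degenerate to -inf
        aic = bic = -np.inf
    return RegressionFit(
        coefficients=pd.Series(beta[1:], index=names),
        intercept=float(beta[0]),
        rss=rss,
        n=n,
        p_predictors=p_eff,
        aic=aic,
        bic=bic,
        rmse_in=float(np.sqrt(rss / n)),
        dropped=dropped,
    )


def _ic(rss: float, n: int, p: int) -> tuple[float, float]:
    if rss <= 0:
        raise ValueError("rss must be positive for Gaussian information criteria")
    base = n * np.log(2 * np.pi * rss / n) + n
    k = p + 2  # slopes + intercept + error variance
    return float(base + 2 * k), float(base + np.log(n) * k)


def information_criteria(fit: RegressionFit) -> tuple[float, float]:
    """Gaussian-ML AIC and BIC of a fitted model.

    ``aic = n ln(2 pi rss/n) + n + 2 (p+2)`` and ``bic`` with ``ln(n)`` in
    place of 2; the additive convention cancels in model differences.
    """
    return _ic(fit.rss, fit.n, fit.p_predictors)


def fit_model1(change: pd.DataFrame, response: str = "SPO2") -> RegressionFit:
    """Raw-trait model: regress the SpO2 change on all other trait changes."""
    if response not in change.columns:
        raise ValueError(f"response column {response!r} missing")
    X = change.drop(columns=[response])
    return fit_ols(X, change[response])


def fit_model2(
    scores: pd.DataFrame, y: pd.Series, *, response_lv: str | None = None
) -> RegressionFit:
    """Composite model: regress the SpO2 change on the non-SpO2 LV scores.

    ``response_lv`` names the LV column to exclude from the predictors (the
    one whose manifest variable is the response); pass None when the score
    matrix already excludes it.
    """
    X = scores.drop(columns=[response_lv]) if response_lv else scores
    return fit_ols(X, y.loc[X.index])


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, folds)):
        assign[idx] = f
    return assign


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int | str = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold (or per-observation for ``folds='loo'``) MSE of OLS prediction.

    Fold membership is a seeded random partition; reuse the same seed across
    models so the paired comparison shares one partition.  Each left-out
    unit is predicted by a model refitted on the remaining observations.
    ``RMSE = sqrt(mean(returned vector))``.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X.values.astype(float)])
    yv = y.values.astype(float)
    if folds == "loo":
        # exact refit via rank-one downdate of the normal equations
        G = A.T @ A
        b = A.T @ yv
        errs = np.empty(n)
        for i in range(n):
            a_i = A[i]
            beta = np.linalg.solve(G - np.outer(a_i, a_i), b - a_i * yv[i])
            errs[i] = (yv[i] - a_i @ beta) ** 2
        return errs
    folds = int(folds)
    if folds < 2:
        raise ValueError("folds must be >= 2 or 'loo'")
    assign = _fold_assignment(n, folds, seed)
    mses = np.empty(folds)
    for f in range(folds):
        test = assign == f
        if test.sum() <= p or (~test).sum() <= p + 1:
            raise ValueError(
                f"fold {f} leaves <= {p} observations on one side; use fewer folds"
            )
        beta, *_ = np.linalg.lstsq(A[~test], yv[~test], rcond=None)
        resid = yv[test] - A[test] @ beta
        mses[f] = float(np.mean(resid**2))
    return mses


def compare_models(
    m1_errors: np.ndarray, m2_errors: np.ndarray
) -> tuple[float, float]:
    """One-sided paired Wilcoxon signed-rank test of ``m1 - m2 > 0``.

    A small p indicates Model 1's paired errors are systematically larger
    (Model 2 fits better).  Exact null enumeration for <= 25 informative
    pairs without ties, otherwise the normal approximation.
    """
    m1 = np.asarray(m1_errors, dtype=float)
    m2 = np.asarray(m2_errors, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("paired error vectors must have equal length")
    d = m1 - m2
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if len(nz) <= 25 and not has_ties else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="greater", method=method,
            correction=(method == "approx"),
        )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModelComparison:
    """Paired evaluation of the raw-trait and composite models."""

    fit_m1: RegressionFit
    fit_m2: RegressionFit
    cv_mse_m1: np.ndarray
    cv_mse_m2: np.ndarray
    loo_mse_m1: np.ndarray
    loo_mse_m2: np.ndarray
    wilcoxon_p_cv: float
    wilcoxon_p_loo: float

    @property
    def cv_rmse(self) -> tuple[float, float]:
        return (float(np.sqrt(self.cv_mse_m1.mean())),
                float(np.sqrt(self.cv_mse_m2.mean())))

    @property
    def loo_rmse(self) -> tuple[float, float]:
        return (float(np.sqrt(self.loo_mse_m1.mean())),
                float(np.sqrt(self.loo_mse_m2.mean())))

    @property
    def winner_by(self) -> dict[str, int]:
        """Winning model (1 or 2) per evaluation index."""
        cv1, cv2 = self.cv_rmse
        loo1, loo2 = self.loo_rmse
        return {
            "aic": 1 if self.fit_m1.aic < self.fit_m2.aic else 2,
            "bic": 1 if self.fit_m1.bic < self.fit_m2.bic else 2,
            "cv_rmse": 1 if cv1 < cv2 else 2,
            "loo_rmse": 1 if loo1 < loo2 else 2,
        }

    def to_dict(self) -> dict:
        cv1, cv2 = self.cv_rmse
        loo1, loo2 = self.loo_rmse
        return {
            "model1": {"aic": self.fit_m1.aic, "bic": self.fit_m1.bic,
                       "cv_rmse": cv1, "loo_rmse": loo1,
                       "n_predictors": self.fit_m1.p_predictors},
            "model2": {"aic": self.fit_m2.aic, "bic": self.fit_m2.bic,
                       "cv_rmse": cv2, "loo_rmse": loo2,
                       "n_predictors": self.fit_m2.p_predictors},
            "wilcoxon_p_cv": self.wilcoxon_p_cv,
            "wilcoxon_p_loo": self.wilcoxon_p_loo,
            "winner_by": self.winner_by,
        }


def compare_model_fits(
    change: pd.DataFrame,
    scores: pd.DataFrame,
    *,
    response: str = "SPO2",
    response_lv: str | None = None,
    folds: int = 10,
    seed: int = 0,
) -> ModelComparison:
    """Fit both models and compare them on a shared CV partition."""
    y = change[response]
    X1 = change.drop(columns=[response])
    X2 = scores.drop(columns=[response_lv]) if response_lv else scores
    X2 = X2.loc[change.index]
    fit1 = fit_model1(change, response)
    fit2 = fit_model2(X2, y)
    cv1 = cross_validate(X1, y, folds, seed)
    cv2 = cross_validate(X2, y, folds, seed)
    loo1 = cross_validate(X1, y, "loo", seed)
    loo2 = cross_validate(X2, y, "loo", seed)
    _, p_cv = compare_models(cv1, cv2)
    _, p_loo = compare_models(loo1, loo2)
    return ModelComparison(fit1, fit2, cv1, cv2, loo1, loo2, p_cv, p_loo)
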