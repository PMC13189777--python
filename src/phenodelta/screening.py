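"""Stage-1 exploratory screen: partial correlations with ΔPhenoAge.

Each lifestyle factor is correlated (Pearson) with the outcome after both
are residualized on a common covariate set (an intercept is always
included).  The main analysis adjusts for sex and the follow-up time ΔAge.
p-values use ``t = r·sqrt((n-2-k)/(1-r²))`` on ``n-2-k`` degrees of freedom;
95% confidence intervals use the Fisher z transform with standard error
``1/sqrt(n-3-k)`` and critical value 1.96.  Factors with p below ``alpha``
(default 0.05, uncorrected — the screen is exploratory) are passed to the
stage-2 subset selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrResult",
    "ScreenReport",
    "SingularCovariatesError",
    "residualize",
    "partial_correlation",
    "screen_factors",
    "PartialCorrelationScreen",
]

_Z95 = 1.96  # normal critical value; at this study's n the t/z gap is negligible


class SingularCovariatesError(np.linalg.LinAlgError):
    """The covariate matrix (with intercept) is rank deficient."""


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial Pearson correlation of one factor with the outcome."""

    factor_name: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    k: int  # number of adjusting covariates


@dataclass
class ScreenReport:
    """All factor results sorted by r, plus the p < alpha selections."""

    results: pd.DataFrame           # factor, r, ci_low, ci_high, p, n, k, selected
    selected_positive: list = field(default_factory=list)
    selected_negative: list = field(default_factory=list)
    alpha: float = 0.05
    dropped: list = field(default_factory=list)  # degenerate (constant) factors

    @property
    def selected(self) -> list:
        return self.selected_positive + self.selected_negative


def _design(covariates, n: int, names=None) -> np.ndarray:
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov.size and cov.shape[0] != n:
        cov = cov.T
    if cov.size and cov.shape[0] != n:
        raise ValueError("covariates and values have unequal lengths")
    X = np.column_stack([np.ones(n), cov]) if cov.size else np.ones((n, 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column not adding rank, for the error message
        labels = ["intercept"] + list(
            names if names is not None else [f"covariate_{j}" for j in range(cov.shape[1])]
        )
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise SingularCovariatesError(
                    f"covariate column {labels[j]!r} is collinear with the preceding columns"
                )
        raise SingularCovariatesError("covariate matrix is rank deficient")
    return X


def residualize(values, covariates=None, covariate_names=None) -> np.ndarray:
    """Least-squares residuals of ``values`` on [intercept | covariates].

    ``values`` may be a vector or an (n, m) matrix of columns to residualize
    against the same covariate set.  Residuals are orthogonal to the
    intercept and every covariate column.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    X = _design(covariates, n, covariate_names)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def partial_correlation(x, y, covariates=None, factor_name: str = "x") -> PartialCorrResult:
    """Partial Pearson correlation of x and y given the covariates.

    Both variables are residualized on [intercept | covariates]; r is the
    Pearson correlation of the residuals.  Degrees of freedom follow the
    ``n - 2 - k`` convention of the standard partial-correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1).shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations (n={n}, k={k})")
    res = residualize(np.column_stack([x, y]), covariates)
    rx, ry = res[:, 0], res[:, 1]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate input: zero residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        p, t = 0.0, np.inf
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), dof)
    se_z = 1.0 / np.sqrt(n - 3 - k)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    ci_low = float(np.tanh(z - _Z95 * se_z))
    ci_high = float(np.tanh(z + _Z95 * se_z))
    return PartialCorrResult(
        factor_name=factor_name, r=r, ci_low=ci_low, ci_high=ci_high,
        p=float(p), n=int(n), k=int(k),
    )


def screen_factors(cohort: pd.DataFrame, outcome: str, covariate_names,
                   factor_names=None, alpha: float = 0.05) -> ScreenReport:
    """Screen every factor for partial correlation with the outcome.

    Returns one result per factor, sorted by r (the forest-plot ordering),
    with the p < alpha factors partitioned by the sign of r.  Constant
    factor columns are excluded with a warning rather than an error.
    """
    covariate_names = list(covariate_names)
    if factor_names is None:
        factor_names = [
            c for c in cohort.columns
            if c != outcome and c not in covariate_names
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    factor_names = list(factor_names)
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    n = len(cohort)
    cov = cohort[covariate_names].to_numpy(dtype=float) if covariate_names else None
    y = cohort[outcome].to_numpy(dtype=float)
    k = len(covariate_names)

    dropped = [f for f in factor_names if cohort[f].nunique() <= 1]
    for f in dropped:
        warnings.warn(f"factor {f!r} is constant and was excluded from the screen")
        logger.warning("factor %r is constant; excluded from screen", f)
    kept = [f for f in factor_names if f not in dropped]

    rows = []
    if kept:
        block = np.column_stack([cohort[f].to_numpy(dtype=float) for f in kept] + [y])
        res = residualize(block, cov, covariate_names)
        ry = res[:, -1]
        sy = np.sqrt(ry @ ry)
        dof = n - 2 - k
        se_z = 1.0 / np.sqrt(n - 3 - k)
        for j, f in enumerate(kept):
            rx = res[:, j]
            sx = np.sqrt(rx @ rx)
            if sx == 0 or sy == 0:
                raise ValueError(f"degenerate residuals for factor {f!r}")
            r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(dof / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), dof))
            with np.errstate(divide="ignore"):
                z = np.arctanh(r)
            rows.append({
                "factor": f, "r": r,
                "ci_low": float(np.tanh(z - _Z95 * se_z)),
                "ci_high": float(np.tanh(z + _Z95 * se_z)),
                "p": p, "n": n, "k": k, "selected": p < alpha,
            })
    results = pd.DataFrame(
        rows, columns=["factor", "r", "ci_low", "ci_high", "p", "n", "k", "selected"]
    ).sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
    pos = results.loc[results.selected & (results.r > 0), "factor"].tolist()
    neg = results.loc[results.selected & (results.r < 0), "factor"].tolist()
    return ScreenReport(results=results, selected_positive=pos,
                        selected_negative=neg, alpha=alpha, dropped=dropped)


class PartialCorrelationScreen(SelectorMixin, BaseEstimator):
    """Feature selector keeping factors partially correlated with the outcome.

    Parameters
    ----------
    covariate_cols : list of str, optional
        Columns of X used as adjusting covariates.  They are excluded from
        screening and never selected by the support mask.
    alpha : float, default 0.05
        Two-sided significance threshold on the partial-correlation test.
    correction : {None, "bonferroni", "bh"}, default None
        Optional multiple-testing correction; off by default to match the
        exploratory-screen convention of raw p < alpha over all factors.
    """

    def __init__(self, covariate_cols=None, alpha: float = 0.05, correction=None):
        self.covariate_cols = covariate_cols
        self.alpha = alpha
        self.correction = correction

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        cov_cols = list(self.covariate_cols or [])
        missing = [c for c in cov_cols if c not in X.columns]
        if missing:
            raise ValueError(f"covariate column(s) {missing} not in X")
        df = X.copy()
        df["__outcome__"] = np.asarray(y, dtype=float)
        report = screen_factors(df, "__outcome__", cov_cols, alpha=self._effective_alpha(X))
        if self.correction == "bh":
            from statsmodels.stats.multitest import multipletests
            rej, *_ = multipletests(report.results["p"], alpha=self.alpha, method="fdr_bh")
            report.results["selected"] = rej
            report.selected_positive = report.results.loc[rej & (report.results.r > 0), "factor"].tolist()
            report.selected_negative = report.results.loc[rej & (report.results.r < 0), "factor"].tolist()
        self.report_ = report
        self.results_ = report.results
        self.selected_ = report.selected
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _effective_alpha(self, X) -> float:
        if self.correction == "bonferroni":
            m = X.shape[1] - len(self.covariate_cols or [])
            return self.alpha / max(m, 1)
        return self.alpha

    def _get_support_mask(self) -> np.ndarray:
        selected = set(self.selected_)
        return np.asarray([c in selected for c in self.feature_names_in_])

    def _more_tags(self):
        return {"allow_nan": False, "requires_y": True}
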