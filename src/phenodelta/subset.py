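"""Stage-2 confirmatory model: exact best-subset OLS minimizing Gaussian AIC.

The search returns the subset of candidate predictors (always including the
forced-in set, ΔAge in the main analysis) whose ordinary least-squares fit
has the smallest AIC among ALL 2^p admissible subsets.  Exactness is the
contract: the default branch-and-bound search exploits the fact that adding
predictors can only lower the residual sum of squares, which yields a valid
lower bound on the AIC attainable within a branch; an exhaustive
enumeration path is provided as an internal cross-check and fallback.

AIC uses the full Gaussian form ``n·ln(rss/n) + n·(ln 2π + 1) + 2·(k + 2)``
(k non-intercept predictors; +2 counts the intercept and the error
variance), matching R's ``AIC()`` on an ``lm`` fit.  Ties are broken toward
fewer predictors, then lexicographic label order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "OlsFit",
    "SubsetModel",
    "RankDeficientError",
    "ols_fit",
    "aic_gaussian",
    "vif",
    "best_subset",
    "effect_contrast",
    "BestSubsetRegressor",
]

_GAUSS_CONST = math.log(2.0 * math.pi) + 1.0
_TIE_TOL = 1e-9


class RankDeficientError(np.linalg.LinAlgError):
    """The design matrix (with intercept) is rank deficient."""


@dataclass(frozen=True)
class OlsFit:
    """An OLS fit with the diagnostics the model report needs."""

    beta: pd.Series       # indexed by ["intercept", *predictors]
    se: pd.Series
    p: pd.Series          # two-sided t-test p-values, n-k-1 dof
    rss: float
    tss: float
    n: int
    k: int                # non-intercept predictors
    r2_adj: float
    aic: float

    @property
    def predictors(self) -> list:
        return [name for name in self.beta.index if name != "intercept"]


@dataclass
class SubsetModel:
    """The AIC-optimal subset, its fit, and collinearity diagnostics."""

    selected: list
    forced: list
    fit: OlsFit
    vif: pd.Series
    search_stats: dict = field(default_factory=dict)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        labels = ["intercept"] + list(names)
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise RankDeficientError(
                    f"design column {labels[j]!r} is collinear with the preceding columns"
                )
        raise RankDeficientError("design matrix is rank deficient")


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """Gaussian AIC: ``n·ln(rss/n) + n·(ln 2π + 1) + 2·(k + 2)``.

    ``k`` counts non-intercept predictors; the penalty counts the intercept
    and the error variance as fitted parameters, matching R's ``AIC(lm(…))``.
    A perfect fit (rss = 0) returns ``-inf`` with a warning, so it dominates
    any selection it appears in.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("rss is exactly zero: AIC is -inf (perfect fit dominates selection)")
        return -math.inf
    return n * math.log(rss / n) + n * _GAUSS_CONST + 2.0 * (k + 2)


def ols_fit(design, outcome, names=None, add_intercept: bool = True) -> OlsFit:
    """OLS with an intercept prepended; SEs from ``rss/(n-k-1)``.

    ``design`` is an (n, k) matrix or DataFrame of predictors (no intercept
    column); ``names`` labels the columns when ``design`` is a bare array.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] == 1 and design.shape[1] > 1 and len(np.asarray(outcome)) > 1:
        design = design.T
    y = np.asarray(outcome, dtype=float)
    n, k = design.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    X = np.column_stack([np.ones(n), design]) if add_intercept else design
    _check_rank(X, names)
    XtX = X.T @ X
    beta = linalg.solve(XtX, X.T @ y, assume_a="pos")
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - k - 1
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(linalg.inv(XtX)), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta + (beta == 0)))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    r2_adj = 1.0 - (rss / dof) / (tss / (n - 1)) if tss > 0 else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = aic_gaussian(rss, n, k)
    index = ["intercept"] + list(names)
    return OlsFit(
        beta=pd.Series(beta, index=index),
        se=pd.Series(se, index=index),
        p=pd.Series(pvals, index=index),
        rss=rss, tss=tss, n=n, k=k, r2_adj=float(r2_adj), aic=float(aic),
    )


def vif(design, names=None) -> pd.Series:
    """Variance inflation factors, ``1/(1 - R²_j)`` per predictor.

    Each predictor is regressed on the others plus an intercept.  Perfect
    collinearity yields ``inf`` for the affected predictors (a flag, not an
    exception).  VIFs are invariant to rescaling any column and equal 1
    exactly when the centered predictors are orthogonal.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    n, k = design.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 non-intercept predictors")
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = np.empty(k)
    for j in range(k):
        yj = design[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(design, j, axis=1)])
        bj, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        rss_j = float(np.sum((yj - Xo @ bj) ** 2))
        tss_j = float(np.sum((yj - yj.mean()) ** 2))
        if tss_j == 0:
            out[j] = np.inf
        else:
            ratio = rss_j / tss_j
            out[j] = np.inf if ratio <= np.finfo(float).eps * n else 1.0 / ratio
    return pd.Series(out, index=names, name="vif")


def _subset_better(aic, k, labels, best) -> bool:
    """Tie-break order: smaller AIC, then fewer predictors, then lexicographic."""
    best_aic, best_k, best_labels = best
    if aic < best_aic - _TIE_TOL:
        return True
    if aic > best_aic + _TIE_TOL:
        return False
    return (k, labels) < (best_k, best_labels)


class _GramSearch:
    """RSS of arbitrary predictor subsets from precomputed Gram matrices.

    The design is [intercept | forced | candidates]; the intercept and
    forced columns are in every admissible subset.
    """

    def __init__(self, y, forced_cols, cand_cols, cand_labels):
        n = len(y)
        blocks = [np.ones((n, 1))]
        if forced_cols is not None and forced_cols.size:
            blocks.append(forced_cols)
        blocks.append(cand_cols)
        Z = np.column_stack(blocks)
        self.n = n
        self.n_base = Z.shape[1] - cand_cols.shape[1]  # intercept + forced
        self.G = Z.T @ Z
        self.c = Z.T @ np.asarray(y, dtype=float)
        self.yy = float(np.asarray(y, dtype=float) @ np.asarray(y, dtype=float))
        self.labels = list(cand_labels)
        self.evals = 0

    def rss(self, cand_idx) -> float:
        """RSS of intercept + forced + the given candidate indices."""
        idx = np.concatenate([np.arange(self.n_base), self.n_base + np.asarray(cand_idx, dtype=int)]) \
            if len(cand_idx) else np.arange(self.n_base)
        Gs = self.G[np.ix_(idx, idx)]
        cs = self.c[idx]
        try:
            cf = linalg.cho_factor(Gs, check_finite=False)
        except np.linalg.LinAlgError:
            raise RankDeficientError("subset design is rank deficient") from None
        b = linalg.cho_solve(cf, cs, check_finite=False)
        self.evals += 1
        return max(self.yy - float(cs @ b), 0.0)


def _aic_of(search: _GramSearch, rss: float, n_forced: int, size: int) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aic_gaussian(rss, search.n, n_forced + size)


def _exhaustive(search: _GramSearch, n_forced: int):
    p = len(search.labels)
    best = (math.inf, math.inf, ())
    best_idx = ()
    examined = 0
    for size in range(p + 1):
        for combo in itertools.combinations(range(p), size):
            examined += 1
            rss = search.rss(combo)
            aic = _aic_of(search, rss, n_forced, size)
            labels = tuple(sorted(search.labels[j] for j in combo))
            if _subset_better(aic, n_forced + size, labels, best):
                best = (aic, n_forced + size, labels)
                best_idx = combo
    return list(best_idx), {"subsets_examined": examined, "subsets_pruned": 0}


def _branch_and_bound(search: _GramSearch, n_forced: int):
    """Exact DFS: a branch with included set I and undecided set U cannot
    beat ``AIC(RSS(I ∪ U), |I|)`` because RSS is monotone nonincreasing in
    the predictor set and the penalty is monotone in size."""
    p = len(search.labels)
    # explore candidates in decreasing marginal-RSS-reduction order: better bounds
    full_rss = search.rss(list(range(p)))
    drops = []
    for j in range(p):
        rss_wo = search.rss([i for i in range(p) if i != j])
        drops.append(rss_wo - full_rss)
    order = sorted(range(p), key=lambda j: -drops[j])

    best = [(math.inf, math.inf, ())]
    best_idx = [()]
    examined = [0]
    pruned = [0]

    def consider(included):
        examined[0] += 1
        rss = search.rss(included)
        aic = _aic_of(search, rss, n_forced, len(included))
        labels = tuple(sorted(search.labels[j] for j in included))
        if _subset_better(aic, n_forced + len(included), labels, best[0]):
            best[0] = (aic, n_forced + len(included), labels)
            best_idx[0] = tuple(included)
        return rss

    def recurse(included, pos):
        # the subtree covers included ∪ (any subset of order[pos:]); every
        # such model has size ≥ |included| and RSS ≥ RSS(included ∪ rest)
        undecided = order[pos:]
        if undecided:
            rss_lb = search.rss(included + undecided)
            aic_lb = _aic_of(search, rss_lb, n_forced, len(included))
            if aic_lb > best[0][0] + _TIE_TOL:
                pruned[0] += 1
                return
        consider(included)
        for q in range(pos, p):
            recurse(included + [order[q]], q + 1)

    recurse([], 0)
    return list(best_idx[0]), {"subsets_examined": examined[0], "subsets_pruned": pruned[0]}


def best_subset(candidates, forced, cohort: pd.DataFrame, outcome: str,
                method: str = "branch_and_bound") -> SubsetModel:
    """Exact AIC-minimizing subset of ``candidates`` with ``forced`` retained.

    Searches all 2^p subsets (p ≤ 30) of the candidate predictors; the
    forced set (ΔAge in the main analysis) is in every admissible model.
    ``method`` is "branch_and_bound" (default) or "exhaustive"; both return
    the same global argmin, with ties broken toward fewer predictors and
    then lexicographic label order.
    """
    candidates = list(candidates)
    forced = list(forced)
    if set(candidates) & set(forced):
        raise ValueError("forced and candidate predictor sets must be disjoint")
    if len(candidates) > 30:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exact-search limit of 30; "
            "tighten the stage-1 screen (smaller alpha) or pre-group predictors"
        )
    missing = [c for c in candidates + forced + [outcome] if c not in cohort.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not in cohort")
    y = cohort[outcome].to_numpy(dtype=float)
    forced_cols = cohort[forced].to_numpy(dtype=float) if forced else np.empty((len(y), 0))
    cand_cols = cohort[candidates].to_numpy(dtype=float) if candidates else np.empty((len(y), 0))
    _check_rank(np.column_stack([np.ones(len(y)), forced_cols, cand_cols]), forced + candidates)

    search = _GramSearch(y, forced_cols, cand_cols, candidates)
    if method == "exhaustive":
        idx, stats_ = _exhaustive(search, len(forced))
    elif method == "branch_and_bound":
        idx, stats_ = _branch_and_bound(search, len(forced))
    else:
        raise ValueError(f"unknown method {method!r}")
    chosen = [candidates[j] for j in sorted(idx)]
    selected = forced + chosen
    fit = ols_fit(cohort[selected], y) if selected else ols_fit(
        np.empty((len(y), 0)), y, names=[])
    vifs = vif(cohort[selected]) if len(selected) >= 2 else pd.Series(dtype=float, name="vif")
    stats_["rss_evaluations"] = search.evals
    return SubsetModel(selected=selected, forced=forced, fit=fit, vif=vifs,
                       search_stats=stats_)


def effect_contrast(fit: OlsFit, predictor: str, delta_units: float) -> float:
    """Outcome change for a ``delta_units`` contrast on one predictor.

    E.g. a 4-point contrast across a 1–5 diet item: beta × 4.
    """
    if predictor not in fit.beta.index:
        raise KeyError(f"predictor {predictor!r} not in fit")
    return float(fit.beta[predictor] * delta_units)


class BestSubsetRegressor(RegressorMixin, BaseEstimator):
    """Exact best-subset OLS (minimum AIC) as a scikit-learn regressor.

    Parameters
    ----------
    forced : list of str, default ()
        Predictor columns retained in every admissible subset.
    method : {"branch_and_bound", "exhaustive"}, default "branch_and_bound"
        Search strategy; both are exact.

    Attributes
    ----------
    selected_ : list of str — forced plus the chosen candidates.
    coef_, se_, p_ : pandas Series over ["intercept", *selected_].
    aic_, r2_adj_ : floats of the selected fit.
    vif_ : Series of variance inflation factors over the selected predictors.
    search_stats_ : dict with subsets examined / pruned.
    """

    def __init__(self, forced=(), method: str = "branch_and_bound"):
        self.forced = forced
        self.method = method

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        forced = list(self.forced)
        candidates = [c for c in X.columns if c not in forced]
        df = X.copy()
        df["__outcome__"] = np.asarray(y, dtype=float)
        model = best_subset(candidates, forced, df, "__outcome__", method=self.method)
        self.model_ = model
        self.selected_ = model.selected
        self.coef_ = model.fit.beta
        self.intercept_ = float(model.fit.beta["intercept"])
        self.se_ = model.fit.se
        self.p_ = model.fit.p
        self.aic_ = model.fit.aic
        self.r2_adj_ = model.fit.r2_adj
        self.vif_ = model.vif
        self.search_stats_ = model.search_stats
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        out = np.full(len(X), self.intercept_)
        for name in self.selected_:
            out = out + self.coef_[name] * X[name].to_numpy(dtype=float)
        return out
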