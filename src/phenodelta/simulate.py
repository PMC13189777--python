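"""Synthetic two-visit cohorts with the structure the analysis assumes.

The generator emulates a Taiwan-Biobank-like table: a sex mix of roughly
36.5% men, a follow-up gap (ΔAge) drawn from a truncated normal whose mean
matches the published per-sex means (4.91 / 4.88 years), the 43 lifestyle
factors with their published marginal distributions (continuous
obesity-index changes, 17 five-point diet items, an education score, three
3-level ordinal items, binary exposure indicators, and the four mutually
exclusive exercise-pattern indicators), and a ΔPhenoAge outcome assembled
from planted linear effects (the published sex-specific regression
coefficients by default) plus Gaussian noise.

Biomarker panels at both visits are then *back-filled* so that scoring them
through :mod:`phenodelta.phenoage` reproduces the planted ΔPhenoAge
exactly: baseline markers are drawn from physiological ranges, and the
follow-up fasting glucose is solved analytically from the affine relation
between the linear predictor and the 6-marker score (glucose carries a
positive weight, so the inversion is one-dimensional and well posed).

Factors are drawn independently by default; real questionnaire items are
of course correlated, so marginals — not joint structure — are what the
defaults reproduce.  An optional Gaussian-copula block can impose a
correlation structure on chosen continuous factors.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phenoage import (
    SEX_MAPPINGS,
    delta_phenoage,
    linear_predictor,
    map_to_phenoage,
    phenoage_from_xb,
    six_marker_spec,
    xb_from_phenoage,
)

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "summarize_cohort",
    "FACTOR_COLUMNS",
    "default_planted_coefficients",
]

SEXES = ("male", "female")

# ---------------------------------------------------------------------------
# Default marginal distributions (published per-sex summaries)
# ---------------------------------------------------------------------------

# follow-up gap in years: truncated normal (mean, sd, low, high)
_DELTA_AGE = {"male": (4.91, 1.51, 1.6, 15.9), "female": (4.88, 1.53, 1.6, 15.9)}
_AGE_BASE = {"male": (50.15, 11.28, 21.0, 90.0), "female": (49.87, 10.41, 21.0, 90.0)}

# changes in obesity indices, (mean, sd); means are follow-up minus baseline
# published means, SDs of the within-person changes are not published and
# are set to realistic short-term tracking values
_CONTINUOUS = {
    "d_bmi": {"male": (0.19, 1.20), "female": (0.27, 1.20)},
    "d_bfp": {"male": (0.12, 3.00), "female": (0.68, 3.20)},
    "d_wc": {"male": (1.02, 4.50), "female": (0.96, 4.50)},
    "d_hc": {"male": (-0.18, 3.50), "female": (0.20, 3.50)},
    "d_whr": {"male": (0.01, 0.040), "female": (0.01, 0.045)},
}

# five-point diet items and the 1-7 education score: discretized truncated
# normals matched to the published follow-up (mean, sd)
_DISCRETE_SCALE = {
    "diet1": {"male": (2.56, 1.61), "female": (3.28, 1.62)},
    "diet2": {"male": (2.82, 1.25), "female": (2.98, 1.32)},
    "diet3": {"male": (2.49, 0.98), "female": (2.63, 1.03)},
    "diet4": {"male": (3.73, 1.25), "female": (4.13, 1.08)},
    "diet5": {"male": (3.87, 0.91), "female": (4.05, 0.85)},
    "diet6": {"male": (4.40, 0.95), "female": (4.42, 0.93)},
    "diet7": {"male": (3.69, 1.21), "female": (3.87, 1.14)},
    "diet8": {"male": (4.29, 0.73), "female": (4.37, 0.68)},
    "diet9": {"male": (3.36, 1.46), "female": (3.21, 1.44)},
    "diet10": {"male": (2.79, 1.43), "female": (2.63, 1.45)},
    "diet11": {"male": (3.54, 1.61), "female": (3.34, 1.64)},
    "diet12": {"male": (3.45, 1.63), "female": (3.58, 1.61)},
    "diet13": {"male": (3.33, 1.47), "female": (3.21, 1.51)},
    "diet14": {"male": (3.22, 1.56), "female": (2.79, 1.59)},
    "diet15": {"male": (3.35, 1.42), "female": (3.02, 1.44)},
    "diet16": {"male": (1.63, 0.94), "female": (1.68, 0.99)},
    "diet17": {"male": (3.64, 1.57), "female": (3.31, 1.67)},
    "education": {"male": (5.75, 0.87), "female": (5.45, 0.96)},
}
_DISCRETE_RANGE = {name: (1, 5) for name in _DISCRETE_SCALE}
_DISCRETE_RANGE["education"] = (1, 7)

# 3-level ordinal items: per-sex category probabilities for levels 1..3
_ORDINAL = {
    "cooking": {"male": (0.714, 0.006, 0.280), "female": (0.217, 0.011, 0.772)},
    "nut": {"male": (0.967, 0.024, 0.009), "female": (0.99907, 0.00077, 0.00016)},
    "supplement": {"male": (0.452, 0.202, 0.346), "female": (0.333, 0.282, 0.385)},
}

# binary exposure indicators: per-sex prevalence
_BINARY = {
    "living_alone": {"male": 0.066, "female": 0.099},
    "job": {"male": 0.677, "female": 0.581},
    "jobsame": {"male": 0.091, "female": 0.085},
    "medication": {"male": 0.006, "female": 0.007},
    "coffee": {"male": 0.473, "female": 0.472},
    "tea": {"male": 0.299, "female": 0.189},
    "drinking": {"male": 0.152, "female": 0.025},
    "smoking": {"male": 0.166, "female": 0.022},
    "smk2nd": {"male": 0.126, "female": 0.079},
    "incense": {"male": 0.231, "female": 0.263},
    "vege": {"male": 0.075, "female": 0.101},
    "supper": {"male": 0.383, "female": 0.308},
}

# exercise pattern at (baseline, follow-up): one categorical draw expanded
# into the four mutually exclusive indicators
_EXERCISE_LEVELS = ("spo_yesyes", "spo_yesno", "spo_noyes", "spo_nono")
_EXERCISE = {
    "male": (0.322, 0.113, 0.131, 0.434),
    "female": (0.288, 0.110, 0.137, 0.465),
}

FACTOR_COLUMNS: tuple = (
    tuple(_CONTINUOUS) + tuple(_DISCRETE_SCALE) + ("chron_age_fu",)
    + tuple(_ORDINAL) + tuple(_BINARY) + _EXERCISE_LEVELS
)  # the 43 screened factors

# baseline biomarker marginals: (mean, sd, low, high) truncated normals
_BIOMARKERS = {
    "mcv": {"male": (90.0, 5.0, 60.0, 120.0), "female": (89.0, 5.5, 60.0, 120.0)},
    "wbc": {"male": (6.3, 1.5, 2.0, 20.0), "female": (6.0, 1.5, 2.0, 20.0)},
    "albumin": {"male": (45.5, 2.4, 30.0, 55.0), "female": (44.5, 2.4, 30.0, 55.0)},
    "creatinine": {"male": (78.0, 14.0, 30.0, 250.0), "female": (60.0, 11.0, 30.0, 250.0)},
    "glucose": {"male": (5.5, 1.0, 3.5, 16.0), "female": (5.3, 0.9, 3.5, 16.0)},
}
# follow-up marker drift SDs (glucose is solved, not drifted)
_DRIFT_SD = {"mcv": 1.5, "wbc": 0.8, "albumin": 1.2, "creatinine": 5.0}
_GLUCOSE_FLOOR = 0.3  # mmol/L; keeps back-filled panels strictly positive

# planted linear effects on ΔPhenoAge (years per predictor unit): the
# published sex-specific multivariable coefficients
_PLANTED = {
    "male": {
        "d_age": 1.2535, "chron_age_fu": 0.0155, "d_bfp": 0.0379, "d_wc": 0.0174,
        "living_alone": 0.4032, "diet2": -0.0672, "diet5": -0.0921,
        "diet16": 0.0941, "diet17": 0.0321, "cooking": 0.0576,
        "incense": 0.2747, "job": -0.1185, "jobsame": -0.3710, "tea": -0.1053,
    },
    "female": {
        "d_age": 1.1960, "chron_age_fu": 0.0236, "d_bmi": 0.1478,
        "diet2": -0.0683, "diet5": -0.0502, "diet16": 0.0664, "diet17": 0.0220,
        "cooking": -0.0566, "incense": 0.1633, "jobsame": -0.0981,
        "supper": 0.0700, "supplement": 0.0462,
    },
}
_TARGET_MEAN_OUTCOME = {"male": 4.75, "female": 4.61}


def default_planted_coefficients() -> dict:
    """Per-sex planted ΔPhenoAge coefficients (published model pattern)."""
    return copy.deepcopy(_PLANTED)


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the study conditions.

    ``planted`` maps sex to {factor (or "d_age"): coefficient}; the outcome
    is the planted linear combination plus Gaussian noise, recentered per
    sex so its mean equals ``target_mean_outcome``.  ``copula_corr`` may
    name a correlation matrix over a subset of continuous factors.
    """

    n: int = 69_462
    sex_fraction_male: float = 25_375 / 69_462
    seed: int = 0
    delta_age: dict = field(default_factory=lambda: copy.deepcopy(_DELTA_AGE))
    age_base: dict = field(default_factory=lambda: copy.deepcopy(_AGE_BASE))
    continuous: dict = field(default_factory=lambda: copy.deepcopy(_CONTINUOUS))
    discrete_scale: dict = field(default_factory=lambda: copy.deepcopy(_DISCRETE_SCALE))
    ordinal: dict = field(default_factory=lambda: copy.deepcopy(_ORDINAL))
    binary: dict = field(default_factory=lambda: copy.deepcopy(_BINARY))
    exercise: dict = field(default_factory=lambda: copy.deepcopy(_EXERCISE))
    biomarkers: dict = field(default_factory=lambda: copy.deepcopy(_BIOMARKERS))
    planted: dict = field(default_factory=default_planted_coefficients)
    noise_sd: float = 3.3
    target_mean_outcome: dict = field(
        default_factory=lambda: dict(_TARGET_MEAN_OUTCOME))
    copula_corr: dict | None = None  # {"factors": [...], "matrix": [[...]]}

    def __post_init__(self) -> None:
        if not 0 <= self.sex_fraction_male <= 1:
            raise ValueError("sex_fraction_male must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        known = set(self.factor_names()) | {"d_age"}
        for sex, coefs in self.planted.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r} in planted coefficients")
            unknown = sorted(set(coefs) - known)
            if unknown:
                raise ValueError(f"planted coefficient(s) name unknown factor(s): {unknown}")
        for name, probs in self.ordinal.items():
            for sex in SEXES:
                p = np.asarray(probs[sex], dtype=float)
                if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=5e-3):
                    raise ValueError(f"ordinal probabilities for {name!r}/{sex} must sum to 1")

    def factor_names(self) -> list:
        """The screened factor roster in canonical column order."""
        return (
            list(self.continuous) + list(self.discrete_scale) + ["chron_age_fu"]
            + list(self.ordinal) + list(self.binary) + list(_EXERCISE_LEVELS)
        )

    def factor_mean(self, name: str, sex: str) -> float:
        """Configured (approximate) marginal mean, used to center the outcome."""
        if name == "d_age":
            return self.delta_age[sex][0]
        if name == "chron_age_fu":
            return self.age_base[sex][0] + self.delta_age[sex][0]
        if name in self.continuous:
            return self.continuous[name][sex][0]
        if name in self.discrete_scale:
            return self.discrete_scale[name][sex][0]
        if name in self.ordinal:
            p = np.asarray(self.ordinal[name][sex], dtype=float)
            return float(np.sum(p / p.sum() * np.arange(1, len(p) + 1)))
        if name in self.binary:
            return float(self.binary[name][sex])
        if name in _EXERCISE_LEVELS:
            return float(self.exercise[sex][_EXERCISE_LEVELS.index(name)])
        raise KeyError(name)


def _solve_truncnorm_loc(mean, sd, low, high) -> float:
    """Location parameter whose [low, high]-truncated N(loc, sd) has the
    given mean (a plain truncated N(mean, sd) is biased when the bounds cut
    into the distribution)."""
    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return optimize.brentq(trunc_mean, mean - 4 * sd, mean + 4 * sd, xtol=1e-10)


def _truncnorm_with_mean(mean, sd, low, high, size, rng) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``."""
    loc = _solve_truncnorm_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _truncnorm_var(mean, sd, low, high) -> float:
    loc = _solve_truncnorm_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return float(stats.truncnorm.var(a, b, loc=loc, scale=sd))


def _discretized_var(mean, sd, low, high) -> float:
    """Exact variance of a rounded-and-clipped normal scale item."""
    levels = np.arange(low, high + 1)
    upper = stats.norm.cdf((levels + 0.5 - mean) / sd)
    lower = stats.norm.cdf((levels - 0.5 - mean) / sd)
    p = upper - lower
    p[0] += lower[0]
    p[-1] += 1.0 - upper[-1]
    mu = float(p @ levels)
    return float(p @ (levels - mu) ** 2)


def factor_variance(config: GeneratorConfig, name: str, sex: str,
                    partial_d_age: bool = True) -> float:
    """Analytic marginal variance of one generated factor.

    For ``chron_age_fu`` with ``partial_d_age=True`` the returned value is
    the variance of its component orthogonal to ΔAge, i.e. the baseline-age
    variance (follow-up age = baseline age + ΔAge with independent draws).
    """
    if name == "d_age":
        return _truncnorm_var(*config.delta_age[sex])
    if name == "chron_age_fu":
        v = _truncnorm_var(*config.age_base[sex])
        if not partial_d_age:
            v += _truncnorm_var(*config.delta_age[sex])
        return v
    if name in config.continuous:
        return float(config.continuous[name][sex][1] ** 2)
    if name in config.discrete_scale:
        low, high = _DISCRETE_RANGE.get(name, (1, 5))
        mean, sd = config.discrete_scale[name][sex]
        return _discretized_var(mean, sd, low, high)
    if name in config.ordinal:
        p = np.asarray(config.ordinal[name][sex], dtype=float)
        p = p / p.sum()
        levels = np.arange(1, len(p) + 1)
        mu = p @ levels
        return float(p @ (levels - mu) ** 2)
    if name in config.binary:
        prev = config.binary[name][sex]
        return float(prev * (1 - prev))
    if name in _EXERCISE_LEVELS:
        prev = config.exercise[sex][_EXERCISE_LEVELS.index(name)]
        return float(prev * (1 - prev))
    raise KeyError(name)


def planted_partial_rho(config: GeneratorConfig, sex: str) -> dict:
    """Planted partial correlation (given ΔAge) of each planted factor.

    Valid for a single-sex stratum with independent factor draws: the
    partial correlation of factor j with the outcome, adjusting for ΔAge,
    is ``β_j·σ_j / σ_resid`` with ``σ_resid²`` the outcome variance left
    after removing the ΔAge component (including factor j's own share).
    """
    coefs = config.planted.get(sex, {})
    variances = {name: factor_variance(config, name, sex)
                 for name in coefs if name != "d_age"}
    resid_var = config.noise_sd ** 2 + sum(
        beta ** 2 * variances[name] for name, beta in coefs.items() if name != "d_age")
    return {name: coefs[name] * np.sqrt(variances[name]) / np.sqrt(resid_var)
            for name in variances}


def _discretized_scale(mean, sd, low, high, size, rng) -> np.ndarray:
    """Integer scale item: rounded truncated normal clipped to [low, high]."""
    x = rng.normal(mean, sd, size=size)
    return np.clip(np.rint(x), low, high).astype(int)


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a reproducible synthetic cohort table.

    Returns one row per participant with sex, chronological ages, the 43
    lifestyle factors, biomarker panels at both visits (columns suffixed
    ``_base``/``_fu``), the scored PhenoAges and the planted ΔPhenoAge.
    Scoring the panels through :mod:`phenodelta.phenoage` reproduces the
    ``delta_phenoage`` column to machine precision by construction.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    spec = six_marker_spec()
    w = spec.weights
    sex = np.where(rng.random(n) < config.sex_fraction_male, "male", "female")
    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(n)], "sex": sex})

    cols: dict = {}
    for name in ("chron_age_base", "d_age"):
        cols[name] = np.empty(n)
    for sx in SEXES:
        m = sex == sx
        if not m.any():
            continue
        cols["chron_age_base"][m] = _truncnorm_with_mean(*config.age_base[sx], m.sum(), rng)
        cols["d_age"][m] = _truncnorm_with_mean(*config.delta_age[sx], m.sum(), rng)
    cols["chron_age_fu"] = cols["chron_age_base"] + cols["d_age"]

    copula = config.copula_corr or {}
    copula_factors = list(copula.get("factors", []))
    if copula_factors:
        corr = np.asarray(copula["matrix"], dtype=float)
        L = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, len(copula_factors))) @ L.T
        u = stats.norm.cdf(z)

    for name, per_sex in config.continuous.items():
        x = np.empty(n)
        for sx in SEXES:
            m = sex == sx
            mean, sd = per_sex[sx]
            if name in copula_factors:
                j = copula_factors.index(name)
                x[m] = stats.norm.ppf(u[m, j], loc=mean, scale=sd)
            else:
                x[m] = rng.normal(mean, sd, size=m.sum())
        cols[name] = x
    for name, per_sex in config.discrete_scale.items():
        low, high = _DISCRETE_RANGE.get(name, (1, 5))
        x = np.empty(n, dtype=int)
        for sx in SEXES:
            m = sex == sx
            mean, sd = per_sex[sx]
            x[m] = _discretized_scale(mean, sd, low, high, m.sum(), rng)
        cols[name] = x
    for name, per_sex in config.ordinal.items():
        x = np.empty(n, dtype=int)
        for sx in SEXES:
            m = sex == sx
            p = np.asarray(per_sex[sx], dtype=float)
            x[m] = rng.choice(np.arange(1, len(p) + 1), size=m.sum(), p=p / p.sum())
        cols[name] = x
    for name, per_sex in config.binary.items():
        x = np.empty(n, dtype=int)
        for sx in SEXES:
            m = sex == sx
            x[m] = (rng.random(m.sum()) < per_sex[sx]).astype(int)
        cols[name] = x
    spo = np.empty(n, dtype=int)
    for sx in SEXES:
        m = sex == sx
        p = np.asarray(config.exercise[sx], dtype=float)
        spo[m] = rng.choice(len(p), size=m.sum(), p=p / p.sum())
    for level, name in enumerate(_EXERCISE_LEVELS):
        cols[name] = (spo == level).astype(int)

    # planted outcome: per-sex linear combination, recentered to the target
    # mean, plus Gaussian noise
    outcome = rng.normal(0.0, config.noise_sd, size=n)
    for sx in SEXES:
        m = sex == sx
        coefs = config.planted.get(sx, {})
        intercept = config.target_mean_outcome[sx] - sum(
            beta * config.factor_mean(name, sx) for name, beta in coefs.items()
        )
        lin = np.full(m.sum(), intercept)
        for name, beta in coefs.items():
            lin += beta * np.asarray(cols[name], dtype=float)[m]
        outcome[m] += lin
    cols["delta_phenoage"] = outcome

    # biomarker panels: baseline drawn, follow-up glucose back-filled so the
    # scored ΔPhenoAge equals the planted outcome exactly
    for name, per_sex in config.biomarkers.items():
        x = np.empty(n)
        for sx in SEXES:
            m = sex == sx
            mean, sd, low, high = per_sex[sx]
            a, b = (low - mean) / sd, (high - mean) / sd
            x[m] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=m.sum(), random_state=rng)
        cols[f"{name}_base"] = x
    for name, drift_sd in _DRIFT_SD.items():
        low = config.biomarkers[name]["male"][2]
        cols[f"{name}_fu"] = np.maximum(
            cols[f"{name}_base"] + rng.normal(0.0, drift_sd, size=n), low)

    offset = np.where(sex == "male", SEX_MAPPINGS["male"].offset, SEX_MAPPINGS["female"].offset)
    slope = np.where(sex == "male", SEX_MAPPINGS["male"].slope, SEX_MAPPINGS["female"].slope)
    base_panel = {
        "mcv": cols["mcv_base"], "wbc": cols["wbc_base"], "albumin": cols["albumin_base"],
        "creatinine": cols["creatinine_base"], "glucose": cols["glucose_base"],
        "chron_age": cols["chron_age_base"],
    }
    six_base = phenoage_from_xb(linear_predictor(base_panel, spec), spec)
    pa_base = offset + slope * six_base
    pa_fu = pa_base + outcome
    xb_fu = xb_from_phenoage((pa_fu - offset) / slope, spec)
    partial = (
        spec.intercept
        + w["mcv"] * cols["mcv_fu"] + w["wbc"] * cols["wbc_fu"]
        + w["albumin"] * cols["albumin_fu"] + w["creatinine"] * cols["creatinine_fu"]
        + w["chron_age"] * cols["chron_age_fu"]
    )
    glucose_fu = (xb_fu - partial) / w["glucose"]
    # positivity guard: raising baseline glucose by d raises the solved
    # follow-up glucose by exactly d (the composition is affine in xb) and
    # leaves the planted ΔPhenoAge untouched
    deficit = np.maximum(_GLUCOSE_FLOOR - glucose_fu, 0.0)
    cols["glucose_base"] = cols["glucose_base"] + deficit
    glucose_fu = glucose_fu + deficit
    pa_base = pa_base + slope * w["glucose"] * deficit / spec.age_rate
    cols["glucose_fu"] = glucose_fu
    cols["phenoage_base"] = pa_base
    cols["phenoage_fu"] = pa_base + outcome

    for name, values in cols.items():
        df[name] = values
    return df


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Per-sex descriptive tables in the published layout.

    Returns ``{"continuous": mean ± SD table, "categorical": count (%)
    table, "negative_delta": fraction of participants whose PhenoAge
    decreased}``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    cat_cols = [c for c in cohort.columns
                if c in set(_ORDINAL) | set(_BINARY) | set(_EXERCISE_LEVELS)]
    num_cols = [c for c in cohort.columns
                if c not in cat_cols + ["id", "sex"]
                and pd.api.types.is_numeric_dtype(cohort[c])]
    cont_rows, cat_rows = [], []
    for sx, grp in cohort.groupby("sex"):
        for c in num_cols:
            cont_rows.append({"sex": sx, "variable": c,
                              "mean": grp[c].mean(), "sd": grp[c].std(ddof=1), "n": len(grp)})
        for c in cat_cols:
            counts = grp[c].value_counts().sort_index()
            for level, count in counts.items():
                cat_rows.append({"sex": sx, "variable": c, "level": level,
                                 "count": int(count), "percent": 100.0 * count / len(grp)})
    neg = {}
    if "delta_phenoage" in cohort.columns:
        for sx, grp in cohort.groupby("sex"):
            neg[sx] = float((grp["delta_phenoage"] < 0).mean())
    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
        "negative_delta": neg,
    }


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Re-score both visits' panels and append PhenoAge/ΔPhenoAge columns.

    Uses the 6-marker score with the sex-specific mapping; the returned
    copy carries ``phenoage_base_scored``, ``phenoage_fu_scored`` and
    ``delta_phenoage_scored``.
    """
    spec = six_marker_spec()
    out = cohort.copy()
    scored = {}
    for visit in ("base", "fu"):
        panel = {
            m: cohort[f"{m}_{visit}"].to_numpy(dtype=float)
            for m in ("mcv", "wbc", "albumin", "creatinine", "glucose")
        }
        panel["chron_age"] = cohort[f"chron_age_{visit}"].to_numpy(dtype=float)
        six = phenoage_from_xb(linear_predictor(panel, spec), spec)
        mapped = np.empty(len(cohort))
        sex = cohort["sex"].to_numpy()
        for sx in SEXES:
            m = sex == sx
            mapped[m] = map_to_phenoage(six[m], sx)
        scored[visit] = mapped
        out[f"phenoage_{visit}_scored"] = mapped
    out["delta_phenoage_scored"] = delta_phenoage(scored["base"], scored["fu"])
    return out
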