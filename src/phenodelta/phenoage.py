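"""Phenotypic-age (PhenoAge) scoring through a Gompertz mortality model.

PhenoAge maps a weighted combination of chronological age and clinical
biomarkers onto an age scale in three steps:

1. a linear predictor ``xb`` (intercept plus weighted marker values),
2. a Gompertz 120-month mortality risk
   ``M = 1 - exp(-exp(xb) * (exp(gamma*h) - 1) / gamma)``,
3. an affine-log-log inversion of the risk onto years,
   ``PhenoAge = c_age + ln(-c_risk * ln(1 - M)) / r``.

The reduced 6-marker variant keeps the intercept and the six weights for
markers measured in the Taiwan Biobank (MCV, WBC, albumin, creatinine,
fasting glucose, chronological age) and drops the remaining four terms.
Sex-specific linear mappings place the 6-marker score back on the full
PhenoAge scale.

Because ``ln(-ln(1 - M)) = xb + ln((exp(gamma*h) - 1)/gamma)``, the composed
score is affine in ``xb``; all internal compositions use this log-survival
form so that risks numerically indistinguishable from 1 never overflow.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerPanel",
    "GompertzModelSpec",
    "SexMapping",
    "PhenoAgeResult",
    "MissingMarkerError",
    "load_model_spec",
    "SEX_MAPPINGS",
    "SIX_MARKERS",
    "linear_predictor",
    "mortality_risk",
    "phenoage_from_risk",
    "six_marker_phenoage",
    "map_to_phenoage",
    "delta_phenoage",
    "PhenoAgeScorer",
]

SIX_MARKERS = ("mcv", "wbc", "albumin", "creatinine", "glucose", "chron_age")


class MissingMarkerError(KeyError):
    """A marker required by the model specification is absent from the panel."""


@dataclass(frozen=True)
class SexMapping:
    """Linear map from the 6-marker score to the full PhenoAge scale."""

    sex: str
    offset: float  # years
    slope: float   # dimensionless, > 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("sex-mapping slope must be positive")

    def __call__(self, six_marker_value):
        return self.offset + self.slope * np.asarray(six_marker_value, dtype=float)


@dataclass(frozen=True)
class GompertzModelSpec:
    """Coefficients of the mortality-score model plus its inversion constants.

    ``weights`` maps marker name to weight on the units of the coefficient
    file; markers in ``log_markers`` enter as their natural log (CRP).
    """

    intercept: float
    weights: Mapping[str, float]
    gamma: float            # per-month Gompertz rate
    horizon: float          # months
    age_const: float        # years
    risk_const: float
    age_rate: float         # per year
    log_markers: frozenset = frozenset()
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def markers(self) -> tuple:
        return tuple(self.weights)

    @property
    def gompertz_scale(self) -> float:
        """(exp(gamma*horizon) - 1) / gamma, the cumulative-hazard factor."""
        return (math.exp(self.gamma * self.horizon) - 1.0) / self.gamma

    def restrict(self, markers) -> "GompertzModelSpec":
        """Reduced spec keeping the intercept and only the given marker terms."""
        missing = [m for m in markers if m not in self.weights]
        if missing:
            raise KeyError(f"markers not in specification: {missing}")
        return GompertzModelSpec(
            intercept=self.intercept,
            weights={m: self.weights[m] for m in markers},
            gamma=self.gamma,
            horizon=self.horizon,
            age_const=self.age_const,
            risk_const=self.risk_const,
            age_rate=self.age_rate,
            log_markers=frozenset(m for m in self.log_markers if m in markers),
            version=f"{self.version}[{','.join(markers)}]",
        )


@dataclass
class BiomarkerPanel:
    """One visit's marker values.

    Units: mcv fL; wbc 10^3 cells/uL; albumin g/L; creatinine umol/L;
    glucose mmol/L; chron_age years; optional lymphocyte_pct %; rdw %;
    alp U/L; crp mg/dL (raw, log-transformed at scoring time).
    """

    mcv: float | None = None
    wbc: float | None = None
    albumin: float | None = None
    creatinine: float | None = None
    glucose: float | None = None
    chron_age: float | None = None
    lymphocyte_pct: float | None = None
    rdw: float | None = None
    alp: float | None = None
    crp: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if name != "crp" and value is not None and value <= 0:
                raise ValueError(f"marker {name!r} must be strictly positive, got {value}")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @property
    def six_marker_complete(self) -> bool:
        return all(getattr(self, m) is not None for m in SIX_MARKERS)


@dataclass(frozen=True)
class PhenoAgeResult:
    """Scored panel: linear predictor, 120-month mortality risk, and years."""

    xb: float
    risk: float
    phenoage: float
    variant: str
    sex_mapping: SexMapping | None = None


def _default_coefficient_path() -> Path:
    return Path(resources.files("phenodelta") / "data" / "levine2018.yaml")


def load_model_spec(path=None, six_marker: bool = False) -> GompertzModelSpec:
    """Load the coefficient file (YAML) into a :class:`GompertzModelSpec`.

    The file's SHA-256 checksum is logged so a run's provenance records which
    coefficient version produced its scores.  With ``six_marker=True`` the
    returned spec keeps only the six Taiwan-Biobank markers.
    """
    path = Path(path) if path is not None else _default_coefficient_path()
    raw = path.read_bytes()
    logger.info("loaded coefficient file %s sha256=%s", path, hashlib.sha256(raw).hexdigest())
    doc = yaml.safe_load(raw)
    weights = {name: float(entry["weight"]) for name, entry in doc["weights"].items()}
    log_markers = frozenset(
        name for name, entry in doc["weights"].items() if entry.get("transform") == "log"
    )
    spec = GompertzModelSpec(
        intercept=float(doc["intercept"]),
        weights=weights,
        gamma=float(doc["gamma"]),
        horizon=float(doc["horizon"]),
        age_const=float(doc["inversion"]["age_const"]),
        risk_const=float(doc["inversion"]["risk_const"]),
        age_rate=float(doc["inversion"]["age_rate"]),
        log_markers=log_markers,
        version=str(doc.get("version", "unversioned")),
    )
    if six_marker:
        spec = spec.restrict(list(doc["six_marker"]["markers"]))
    return spec


def _load_sex_mappings() -> dict:
    doc = yaml.safe_load(_default_coefficient_path().read_bytes())
    return {
        sex: SexMapping(sex=sex, offset=float(m["offset"]), slope=float(m["slope"]))
        for sex, m in doc["sex_mapping"].items()
    }


SEX_MAPPINGS: dict = _load_sex_mappings()

_FULL_SPEC = load_model_spec()
_SIX_MARKER_SPEC = load_model_spec(six_marker=True)


def full_model_spec() -> GompertzModelSpec:
    """The 10-term (9 biomarkers + chronological age) specification."""
    return _FULL_SPEC


def six_marker_spec() -> GompertzModelSpec:
    """The reduced specification over the six Taiwan-Biobank markers."""
    return _SIX_MARKER_SPEC


def _panel_values(panel) -> dict:
    if isinstance(panel, BiomarkerPanel):
        return panel.as_dict()
    if isinstance(panel, pd.Series):
        return {k: v for k, v in panel.items() if v is not None and not pd.isna(v)}
    return dict(panel)


def linear_predictor(panel, spec: GompertzModelSpec):
    """Intercept plus weighted sum of the spec's marker values.

    ``panel`` may be a :class:`BiomarkerPanel`, a mapping, or a mapping of
    arrays (vectorized scoring).  Markers the spec does not cover are
    ignored; a covered marker that is absent raises
    :class:`MissingMarkerError`.  CRP (when covered) enters as its natural
    log and must be strictly positive.
    """
    values = _panel_values(panel)
    xb = np.asarray(spec.intercept, dtype=float)
    for marker, weight in spec.weights.items():
        if marker not in values:
            raise MissingMarkerError(f"panel is missing required marker {marker!r}")
        v = np.asarray(values[marker], dtype=float)
        if marker in spec.log_markers:
            if np.any(v <= 0):
                raise ValueError(f"marker {marker!r} must be positive for log transform")
            v = np.log(v)
        xb = xb + weight * v
    return xb if xb.ndim else float(xb)


def log_survival(xb, spec: GompertzModelSpec):
    """ln(1 - M): the log of 120-month survival, exact for any finite xb."""
    xb = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb)):
        raise ValueError("linear predictor must be finite")
    out = -np.exp(xb) * spec.gompertz_scale
    return out if out.ndim else float(out)


def mortality_risk(xb, spec: GompertzModelSpec):
    """Gompertz probability of death within the model horizon (120 months).

    ``M = 1 - exp(-exp(xb) * (exp(gamma*h) - 1)/gamma)``; strictly
    increasing in ``xb`` and in (0, 1) for any finite ``xb`` (up to floating
    point saturation very far above the physiological range).
    """
    out = -np.expm1(log_survival(xb, spec))
    return out if np.ndim(out) else float(out)


def phenoage_from_risk(risk, spec: GompertzModelSpec):
    """Invert a mortality risk onto the age scale (years).

    Applies ``c_age + ln(-c_risk * ln(1 - M)) / r``; strictly increasing
    in the risk, defined for risk strictly inside (0, 1).
    """
    risk = np.asarray(risk, dtype=float)
    if np.any(~np.isfinite(risk)) or np.any(risk <= 0) or np.any(risk >= 1):
        raise ValueError("risk must lie strictly inside (0, 1)")
    out = spec.age_const + np.log(-spec.risk_const * np.log1p(-risk)) / spec.age_rate
    return out if out.ndim else float(out)


def phenoage_from_xb(xb, spec: GompertzModelSpec):
    """Compose risk and inversion in log-survival space (no overflow).

    Algebraically identical to ``phenoage_from_risk(mortality_risk(xb))``:
    the composition is affine, ``c_age + (ln c_risk + ln s + xb) / r`` with
    ``s`` the cumulative-hazard factor.
    """
    xb = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb)):
        raise ValueError("linear predictor must be finite")
    out = spec.age_const + (
        math.log(spec.risk_const) + math.log(spec.gompertz_scale) + xb
    ) / spec.age_rate
    return out if out.ndim else float(out)


def xb_from_phenoage(phenoage, spec: GompertzModelSpec):
    """Inverse of :func:`phenoage_from_xb` (used by the cohort generator)."""
    phenoage = np.asarray(phenoage, dtype=float)
    out = spec.age_rate * (phenoage - spec.age_const) - (
        math.log(spec.risk_const) + math.log(spec.gompertz_scale)
    )
    return out if out.ndim else float(out)


def six_marker_phenoage(panel, spec: GompertzModelSpec | None = None):
    """Reduced PhenoAge from MCV, WBC, albumin, creatinine, glucose and age.

    Equals ``phenoage_from_risk(mortality_risk(linear_predictor(panel)))``
    under the six-marker specification, evaluated in log-survival space.
    """
    if spec is None:
        spec = _SIX_MARKER_SPEC
    return phenoage_from_xb(linear_predictor(panel, spec), spec)


def map_to_phenoage(six_marker_value, sex: str):
    """Sex-specific linear mapping of the 6-marker score to PhenoAge years."""
    try:
        mapping = SEX_MAPPINGS[sex]
    except KeyError:
        raise ValueError(
            f"unknown sex code {sex!r}; expected one of {sorted(SEX_MAPPINGS)}"
        ) from None
    out = mapping(six_marker_value)
    return out if np.ndim(out) else float(out)


def delta_phenoage(baseline, followup):
    """Within-individual change: PhenoAge at follow-up minus at baseline."""
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if not (np.all(np.isfinite(baseline)) and np.all(np.isfinite(followup))):
        raise ValueError("PhenoAge values must be finite")
    out = followup - baseline
    return out if out.ndim else float(out)


def score_panel(panel, sex: str | None = None, variant: str = "mapped") -> PhenoAgeResult:
    """Score one panel, returning xb, risk and PhenoAge.

    ``variant`` is ``"six_marker"`` (raw reduced score), ``"mapped"``
    (reduced score through the sex mapping; requires ``sex``) or ``"full9"``
    (all ten Levine terms; requires the optional markers).
    """
    if variant == "full9":
        spec = _FULL_SPEC
    elif variant in ("six_marker", "mapped"):
        spec = _SIX_MARKER_SPEC
    else:
        raise ValueError(f"unknown variant {variant!r}")
    xb = linear_predictor(panel, spec)
    risk = mortality_risk(xb, spec)
    age = phenoage_from_xb(xb, spec)
    mapping = None
    if variant == "mapped":
        if sex is None:
            raise ValueError("variant 'mapped' requires a sex code")
        mapping = SEX_MAPPINGS.get(sex)
        age = map_to_phenoage(age, sex)
    return PhenoAgeResult(xb=xb, risk=risk, phenoage=age, variant=variant, sex_mapping=mapping)


class PhenoAgeScorer(TransformerMixin, BaseEstimator):
    """Transformer scoring biomarker columns of a DataFrame into PhenoAge years.

    Parameters
    ----------
    variant : {"mapped", "six_marker", "full9"}, default "mapped"
        Which score to produce.  "mapped" applies the sex-specific linear
        mapping and needs a ``sex_col`` with values "male"/"female".
    sex_col : str, default "sex"
        Column holding the sex code (used only by the mapped variant).
    coefficients : str or Path, optional
        Alternative coefficient YAML; defaults to the packaged Levine 2018
        file.
    column_map : dict, optional
        Maps canonical marker names to the DataFrame's column names.
    """

    def __init__(self, variant: str = "mapped", sex_col: str = "sex",
                 coefficients=None, column_map: dict | None = None):
        self.variant = variant
        self.sex_col = sex_col
        self.coefficients = coefficients
        self.column_map = column_map

    def fit(self, X: pd.DataFrame, y=None):
        if self.variant not in ("mapped", "six_marker", "full9"):
            raise ValueError(f"unknown variant {self.variant!r}")
        spec = load_model_spec(self.coefficients, six_marker=self.variant != "full9")
        colmap = dict(self.column_map or {})
        missing = [
            m for m in spec.markers if colmap.get(m, m) not in X.columns
        ]
        if missing:
            raise MissingMarkerError(f"panel is missing required marker(s) {missing}")
        if self.variant == "mapped" and self.sex_col not in X.columns:
            raise ValueError(f"mapped variant requires a {self.sex_col!r} column")
        self.model_spec_ = spec
        self.column_map_ = colmap
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Return an (n, 1) array of PhenoAge years."""
        spec = self.model_spec_
        values = {m: X[self.column_map_.get(m, m)].to_numpy(dtype=float)
                  for m in spec.markers}
        ages = phenoage_from_xb(linear_predictor(values, spec), spec)
        if self.variant == "mapped":
            sex = X[self.sex_col].to_numpy()
            out = np.empty(len(X), dtype=float)
            for code, mapping in SEX_MAPPINGS.items():
                out[sex == code] = mapping(ages[sex == code])
            unknown = ~np.isin(sex, list(SEX_MAPPINGS))
            if unknown.any():
                raise ValueError(f"unknown sex code(s): {sorted(set(sex[unknown]))}")
            ages = out
        return np.asarray(ages, dtype=float).reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"phenoage_{self.variant}"], dtype=object)
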