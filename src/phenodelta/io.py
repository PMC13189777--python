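"""Cohort CSV ingestion, unit conversion, validation and provenance output.

The cohort is a plain CSV, one row per participant, with missing values as
empty fields.  A :class:`PipelineConfig` names the dataset's columns, the
unit each biomarker column is recorded in (converted to the scoring units
at ingest — unit mistakes are the dominant failure mode for this score),
the outcome/covariate/factor declarations, and the run parameters.  Every
output file carries a provenance header (seed, config hash, software and
coefficient versions) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "UNIT_CONVERSIONS",
    "read_cohort",
    "write_csv_with_provenance",
    "read_provenance_csv",
]

# canonical scoring units: mcv fL, wbc 10^3 cells/uL, albumin g/L,
# creatinine umol/L, glucose mmol/L, crp mg/dL
UNIT_CONVERSIONS = {
    ("albumin", "g/L"): 1.0,
    ("albumin", "g/dL"): 10.0,
    ("creatinine", "umol/L"): 1.0,
    ("creatinine", "mg/dL"): 88.42,
    ("glucose", "mmol/L"): 1.0,
    ("glucose", "mg/dL"): 1.0 / 18.016,
    ("wbc", "10^3 cells/uL"): 1.0,
    ("wbc", "10^9 cells/L"): 1.0,
    ("wbc", "cells/uL"): 1e-3,
    ("mcv", "fL"): 1.0,
    ("crp", "mg/dL"): 1.0,
    ("crp", "mg/L"): 0.1,
}


class SchemaError(ValueError):
    """The cohort file does not match the declared schema."""


@dataclass
class PipelineConfig:
    """Declarative configuration of the end-to-end pipeline.

    ``column_map`` maps dataset column names to canonical names;
    ``units`` maps (canonical) biomarker column names to their recorded
    unit; ``sex_codes`` maps dataset sex codes to "male"/"female".
    """

    column_map: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    outcome: str = "delta_phenoage_scored"
    covariates: list = field(default_factory=lambda: ["sex_indicator", "d_age"])
    factors: list | None = None          # None -> the generator's 43-factor roster
    alpha: float = 0.05
    forced: list = field(default_factory=lambda: ["d_age"])
    sex_col: str = "sex"
    sex_codes: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "phenodelta_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        seen: dict = {}
        for src, dst in self.column_map.items():
            if dst in seen:
                raise ValueError(f"column {dst!r} mapped twice ({seen[dst]!r} and {src!r})")
            seen[dst] = src

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant fields (output location excluded)."""
        doc = asdict(self)
        doc.pop("output_dir", None)
        payload = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _marker_of(column: str) -> str | None:
    base = column.removesuffix("_base").removesuffix("_fu")
    return base if any(base == m for m, _ in UNIT_CONVERSIONS) else None


def read_cohort(path, config: PipelineConfig | None = None,
                required: list | None = None) -> pd.DataFrame:
    """Read, rename, unit-convert and complete-case-filter a cohort CSV.

    ``required`` lists canonical columns that must exist (defaults to every
    column the config declares); rows missing any required value are
    dropped once, with the count logged.  Unparseable numeric cells raise a
    row-level error naming the file line.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if config.column_map:
        df = df.rename(columns=config.column_map)
    if required is None:
        required = [c for c in ([config.outcome] if config.outcome in df.columns else [])
                    + list(config.factors or []) + list(config.units)]
        required = [c for c in dict.fromkeys(required)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file is missing declared column(s): {missing}")

    numeric_like = [c for c in required
                    if c in df.columns and c not in (config.sex_col, "id")
                    and df[c].dtype == object]
    for c in numeric_like:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].notna() & df[c].astype(str).str.strip().ne("") & coerced.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise SchemaError(f"unparseable value {df.loc[df.index[bad][0], c]!r} "
                              f"in column {c!r} at line {line}")
        df[c] = coerced

    for col, unit in config.units.items():
        marker = _marker_of(col)
        if marker is None:
            raise SchemaError(f"units declared for unknown biomarker column {col!r}")
        try:
            factor = UNIT_CONVERSIONS[(marker, unit)]
        except KeyError:
            raise SchemaError(f"no conversion for {marker!r} from unit {unit!r}") from None
        if col in df.columns:
            df[col] = df[col] * factor

    if config.sex_codes and config.sex_col in df.columns:
        df[config.sex_col] = df[config.sex_col].map(
            lambda v: config.sex_codes.get(v, v))

    check_cols = [c for c in required if c in df.columns] or list(df.columns)
    before = len(df)
    df = df.dropna(subset=check_cols).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("complete-case filter dropped %d of %d rows", dropped, before)
    df.attrs["n_dropped"] = dropped
    return df


def write_csv_with_provenance(df: pd.DataFrame, path, meta: dict) -> None:
    """Write a CSV with ``# key: value`` provenance comment lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_provenance_csv(path) -> tuple:
    """Read a provenance-headed CSV; returns (DataFrame, meta dict)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return pd.read_csv(path, comment="#"), meta
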