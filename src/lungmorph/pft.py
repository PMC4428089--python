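"""Spirometry-derived metrics: postural drop, weakness and hypercapnia flags,
and validated cohort tables.

Spirometry volumes arrive as percent predicted (reference equations are
upstream of this package).  The postural drop

    dFVC = (FVC_sitting - FVC_supine) / FVC_sitting * 100%

is scale-invariant, so percent-predicted and absolute-litre inputs give
the same value.  A drop strictly above 25% is flagged as suggestive of
diaphragmatic weakness, and a daytime expiratory CO2 strictly above
6.0 kPa as suggestive of hypercapnia / chronic alveolar hypoventilation.
Boundary values do not flag; negative drops (supine better than sitting)
are kept and flagged paradoxical, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WEAKNESS_THRESHOLD_PCT = 25.0
HYPERCAPNIA_THRESHOLD_KPA = 6.0

MANDATORY_COLUMNS = ("subject_id", "group")
NUMERIC_COLUMNS = (
    "fvc_sitting_pct", "fvc_supine_pct",
    "fev1_sitting_pct", "fev1_supine_pct",
    "mip_kpa", "mep_kpa", "co2_kpa",
)
GROUPS = ("patient", "control")


def postural_drop(fvc_sitting: float, fvc_supine: float) -> float:
    """Postural drop of FVC in percent, signed."""
    if fvc_sitting <= 0:
        raise ValueError(f"fvc_sitting must be positive, got {fvc_sitting}")
    return (fvc_sitting - fvc_supine) / fvc_sitting * 100.0


def flag_weakness(delta_fvc: float) -> bool:
    """True when the postural drop strictly exceeds 25%."""
    if not np.isfinite(delta_fvc):
        raise ValueError("delta_fvc must be finite")
    return delta_fvc > WEAKNESS_THRESHOLD_PCT


def flag_hypercapnia(co2_kpa: float) -> bool:
    """True when expiratory CO2 strictly exceeds 6.0 kPa."""
    if co2_kpa < 0:
        raise ValueError("CO2 fraction cannot be negative")
    return co2_kpa > HYPERCAPNIA_THRESHOLD_KPA


@dataclass
class SpirometryRecord:
    subject_id: str
    group: str
    fvc_sitting_pct: float | None = None
    fvc_supine_pct: float | None = None
    fev1_sitting_pct: float | None = None
    fev1_supine_pct: float | None = None
    mip_kpa: float | None = None
    mep_kpa: float | None = None
    co2_kpa: float | None = None
    delta_fvc_pct: float | None = None
    weakness_flag: bool | None = None
    hypercapnia_flag: bool | None = None
    paradoxical_drop: bool = False

    def derive(self) -> "SpirometryRecord":
        if self.fvc_sitting_pct is not None and self.fvc_supine_pct is not None:
            self.delta_fvc_pct = postural_drop(self.fvc_sitting_pct,
                                               self.fvc_supine_pct)
            self.weakness_flag = flag_weakness(self.delta_fvc_pct)
            self.paradoxical_drop = self.delta_fvc_pct < 0
        if self.co2_kpa is not None and np.isfinite(self.co2_kpa):
            self.hypercapnia_flag = flag_hypercapnia(self.co2_kpa)
        return self


@dataclass
class CohortTable:
    """Validated cohort spirometry table with derived columns."""

    frame: pd.DataFrame
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def group(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == name]


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    errors: list[str] = []
    warnings: list[str] = []
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            warnings.append(f"optional column missing: {col}")
            df[col] = np.nan
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        for idx in df.index[bad]:
            errors.append(
                f"row {idx} ({df.loc[idx, 'subject_id']}): non-numeric "
                f"{col} = {df.loc[idx, col]!r}")
        df[col] = coerced
    for col in [c for c in df.columns if c.endswith("_pct")
                and not c.startswith("delta")]:
        out_of_range = df[col].notna() & ~df[col].between(0, 200)
        for idx in df.index[out_of_range]:
            errors.append(
                f"row {idx} ({df.loc[idx, 'subject_id']}): {col} = "
                f"{df.loc[idx, col]} outside [0, 200] percent predicted")
    for col in ("mip_kpa", "mep_kpa", "co2_kpa"):
        neg = df[col].notna() & (df[col] < 0)
        for idx in df.index[neg]:
            errors.append(f"row {idx}: negative pressure/CO2 in {col}")
    unknown = set(df["group"].dropna()) - set(GROUPS)
    if unknown:
        errors.append(f"unknown group labels: {sorted(unknown)} "
                      f"(expected {GROUPS})")
    return df, errors, warnings


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Populate delta_fvc_pct and the weakness/hypercapnia flags."""
    df = df.copy()
    both = df["fvc_sitting_pct"].notna() & df["fvc_supine_pct"].notna() \
        & (df["fvc_sitting_pct"] > 0)
    df["delta_fvc_pct"] = np.nan
    df.loc[both, "delta_fvc_pct"] = (
        (df.loc[both, "fvc_sitting_pct"] - df.loc[both, "fvc_supine_pct"])
        / df.loc[both, "fvc_sitting_pct"] * 100.0)
    df["weakness_flag"] = (df["delta_fvc_pct"]
                           > WEAKNESS_THRESHOLD_PCT).astype("boolean")
    df.loc[df["delta_fvc_pct"].isna(), "weakness_flag"] = pd.NA
    df["paradoxical_drop"] = df["delta_fvc_pct"] < 0
    df["hypercapnia_flag"] = (df["co2_kpa"]
                              > HYPERCAPNIA_THRESHOLD_KPA).astype("boolean")
    df.loc[df["co2_kpa"].isna(), "hypercapnia_flag"] = pd.NA
    return df


def load_cohort(path: str | Path | pd.DataFrame) -> CohortTable:
    """Load and validate a cohort spirometry CSV (or DataFrame).

    Mandatory columns: subject_id, group ("patient"/"control").  Numeric
    columns are validated row by row; rows with missing optional values
    are kept with the derived fields left absent.  A header-only file
    yields an empty table with a warning, not an error.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing mandatory columns: {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    df, errors, warnings = _validate_rows(df)
    if len(df) == 0:
        warnings.append("cohort table has a header but no rows")
        log.warning("empty cohort table")
        return CohortTable(frame=df, errors=errors, warnings=warnings)
    n_missing_supine = int(df["fvc_supine_pct"].isna().sum())
    if n_missing_supine:
        warnings.append(
            f"{n_missing_supine} row(s) missing fvc_supine_pct; "
            "delta_fvc left undefined there")
    df = derive_columns(df)
    for msg in warnings:
        log.warning(msg)
    return CohortTable(frame=df, errors=errors, warnings=warnings)


def save_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index=False)
    return path
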