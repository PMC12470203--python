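"""Domain types, tidy CSV I/O, and validation for soil, organ, and infusion tables.

Unit conventions (enforced throughout the package):

* soil totals (Cd, Se)            mg kg-1
* soil available fractions        ug kg-1  (DTPA-Cd, NaHCO3-Se)
* plant-organ concentrations      mg kg-1  dry weight
* infusion concentrations         ug L-1

The ug <-> mg factor of 1000 is applied exactly once, inside the index
formulas that need it (:mod:`teatrace.transfer_indices`), never in I/O.
Missing values travel as empty CSV cells / NaN and are propagated, not
zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "ELEMENTS",
    "SOIL_COLUMNS",
    "ORGAN_COLUMNS",
    "INFUSION_COLUMNS",
    "BrewSpec",
    "SoilSample",
    "OrganMeasurement",
    "InfusionMeasurement",
    "TransferSummary",
    "Study",
    "SchemaError",
    "StudyValidationError",
    "read_soil",
    "read_organs",
    "read_infusion",
    "read_study",
    "write_study",
]

#: Closed vocabulary of tea-tree compartments, ordered root -> leaf.
ORGANS = (
    "fibrous_root",
    "taproot",
    "main_stem",
    "lateral_stem",
    "old_leaf",
    "young_leaf",
)

ELEMENTS = ("Cd", "Se")

SOIL_COLUMNS = [
    "site_id",
    "cd_total_mg_kg",
    "cd_avail_ug_kg",
    "se_total_mg_kg",
    "se_avail_ug_kg",
    "ph",
    "som_g_kg",
    "tn_g_kg",
    "tp_g_kg",
    "ap_mg_kg",
    "ak_mg_kg",
]
ORGAN_COLUMNS = ["site_id", "organ", "element", "replicate", "conc_mg_kg"]
INFUSION_COLUMNS = ["site_id", "element", "conc_ug_L", "tea_mass_kg", "water_volume_L"]


class SchemaError(ValueError):
    """A CSV is missing required columns or has the wrong header."""


class StudyValidationError(ValueError):
    """One or more rows violate a table invariant.

    ``errors`` holds one human-readable message per offending row,
    each prefixed with the 1-based data row number.
    """

    def __init__(self, table: str, errors: list[str]):
        self.table = table
        self.errors = errors
        msg = f"{table}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        super().__init__(msg)


@dataclass(frozen=True)
class BrewSpec:
    """One steeping: dry-tea mass infused into a fixed water volume.

    Defaults are the standard assay brew: 5.000 g green tea in 100 mL
    boiling water for 10 min.
    """

    tea_mass: float = 0.005  # kg
    water_volume: float = 0.100  # L
    steep_minutes: float = 10.0
    water_temp: float = 100.0  # degC

    def __post_init__(self) -> None:
        if not self.tea_mass > 0:
            raise ValueError(f"tea_mass must be > 0, got {self.tea_mass}")
        if not self.water_volume > 0:
            raise ValueError(f"water_volume must be > 0, got {self.water_volume}")


@dataclass
class SoilSample:
    """One site's soil chemistry: element pools plus optional agronomic covariates."""

    site_id: str
    cd_total: float  # mg/kg
    cd_avail: float  # ug/kg
    se_total: float  # mg/kg
    se_avail: float  # ug/kg
    ph: float | None = None
    som: float | None = None  # g/kg
    tn: float | None = None  # g/kg
    tp: float | None = None  # g/kg
    ap: float | None = None  # mg/kg
    ak: float | None = None  # mg/kg


@dataclass
class OrganMeasurement:
    site_id: str
    organ: str
    element: str
    concentration: float  # mg/kg DW
    replicate: int = 1


@dataclass
class InfusionMeasurement:
    site_id: str
    element: str
    concentration: float  # ug/L
    brew: BrewSpec = field(default_factory=BrewSpec)


@dataclass(frozen=True)
class TransferSummary:
    """mean +/- sd of an index within one group (site, organ, or organ pair)."""

    group: str
    n: int
    mean: float
    sd: float | None = None
    letters: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd is not None and not math.isnan(self.sd):
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
            if self.n < 2:
                raise ValueError("sd requires n >= 2")


@dataclass
class Study:
    """A validated study bundle: one soil table, one organ table, one infusion table."""

    soil: pd.DataFrame
    organs: pd.DataFrame
    infusion: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.soil["site_id"])


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _check(errors: list[str], row: int, ok: bool, msg: str) -> None:
    if not ok:
        errors.append(f"row {row}: {msg}")


def read_soil(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy soil table (one row per site)."""
    df = pd.read_csv(path)
    _require_columns(df, SOIL_COLUMNS[:5], "soil")
    for col in SOIL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SOIL_COLUMNS]
    df["site_id"] = df["site_id"].astype(str)

    errors: list[str] = []
    dup = df["site_id"].duplicated()
    for i in df.index[dup]:
        errors.append(f"row {i + 1}: duplicate site_id {df.at[i, 'site_id']!r}")
    for i, rec in df.iterrows():
        row = i + 1
        _check(errors, row, rec["cd_total_mg_kg"] > 0, "cd_total_mg_kg must be > 0")
        _check(errors, row, rec["se_total_mg_kg"] > 0, "se_total_mg_kg must be > 0")
        for col in ("cd_avail_ug_kg", "se_avail_ug_kg"):
            if not pd.isna(rec[col]):
                _check(errors, row, rec[col] >= 0, f"{col} must be >= 0")
        if not pd.isna(rec["ph"]):
            _check(errors, row, 3.0 <= rec["ph"] <= 10.0, "ph outside plausible range [3, 10]")
    if errors:
        raise StudyValidationError("soil", errors)
    return df.reset_index(drop=True)


def read_organs(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy organ table (one measurement per row)."""
    df = pd.read_csv(path)
    _require_columns(df, ORGAN_COLUMNS, "organs")
    df = df[ORGAN_COLUMNS]
    if df.empty:
        return df.assign(site_id=df["site_id"].astype(str))
    df["site_id"] = df["site_id"].astype(str)

    errors: list[str] = []
    key = ["site_id", "organ", "element", "replicate"]
    dup = df.duplicated(subset=key)
    for i in df.index[dup]:
        errors.append(f"row {i + 1}: duplicate key {tuple(df.loc[i, key])}")
    for i, rec in df.iterrows():
        row = i + 1
        _check(errors, row, rec["organ"] in ORGANS,
               f"unknown organ {rec['organ']!r}; expected one of {ORGANS}")
        _check(errors, row, rec["element"] in ELEMENTS,
               f"unknown element {rec['element']!r}; expected one of {ELEMENTS}")
        if not pd.isna(rec["conc_mg_kg"]):
            _check(errors, row, rec["conc_mg_kg"] >= 0, "conc_mg_kg must be >= 0")
    if errors:
        raise StudyValidationError("organs", errors)
    return df.reset_index(drop=True)


def read_infusion(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy infusion table (one site x element per row)."""
    df = pd.read_csv(path)
    _require_columns(df, INFUSION_COLUMNS[:3], "infusion")
    if "tea_mass_kg" not in df.columns:
        df["tea_mass_kg"] = BrewSpec().tea_mass
    if "water_volume_L" not in df.columns:
        df["water_volume_L"] = BrewSpec().water_volume
    df = df[INFUSION_COLUMNS]
    if df.empty:
        return df.assign(site_id=df["site_id"].astype(str))
    df["site_id"] = df["site_id"].astype(str)

    errors: list[str] = []
    dup = df.duplicated(subset=["site_id", "element"])
    for i in df.index[dup]:
        errors.append(f"row {i + 1}: duplicate (site_id, element) "
                      f"{(df.at[i, 'site_id'], df.at[i, 'element'])}")
    for i, rec in df.iterrows():
        row = i + 1
        _check(errors, row, rec["element"] in ELEMENTS,
               f"unknown element {rec['element']!r}; expected one of {ELEMENTS}")
        if not pd.isna(rec["conc_ug_L"]):
            _check(errors, row, rec["conc_ug_L"] >= 0, "conc_ug_L must be >= 0")
        _check(errors, row, rec["tea_mass_kg"] > 0, "tea_mass_kg must be > 0")
        _check(errors, row, rec["water_volume_L"] > 0, "water_volume_L must be > 0")
    if errors:
        raise StudyValidationError("infusion", errors)
    return df.reset_index(drop=True)


def read_study(soil_path: str | Path, organ_path: str | Path,
               infusion_path: str | Path) -> Study:
    """Read the three study tables, validating each; returns a :class:`Study`."""
    return Study(
        soil=read_soil(soil_path),
        organs=read_organs(organ_path),
        infusion=read_infusion(infusion_path),
    )


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write a study bundle to ``out_dir`` as soil.csv / organs.csv / infusion.csv.

    Missing values are written as empty cells. Round-trips through
    :func:`read_study` up to float formatting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "soil": out / "soil.csv",
        "organs": out / "organs.csv",
        "infusion": out / "infusion.csv",
    }
    study.soil.to_csv(paths["soil"], index=False)
    study.organs.to_csv(paths["organs"], index=False)
    study.infusion.to_csv(paths["infusion"], index=False)
    return paths


def soil_samples(soil: pd.DataFrame) -> list[SoilSample]:
    """View a soil table as typed records (optional covariates -> None)."""
    out = []
    for _, r in soil.iterrows():
        kwargs = dict(
            site_id=r["site_id"],
            cd_total=r["cd_total_mg_kg"],
            cd_avail=r["cd_avail_ug_kg"],
            se_total=r["se_total_mg_kg"],
            se_avail=r["se_avail_ug_kg"],
        )
        for name, col in (("ph", "ph"), ("som", "som_g_kg"), ("tn", "tn_g_kg"),
                          ("tp", "tp_g_kg"), ("ap", "ap_mg_kg"), ("ak", "ak_mg_kg")):
            v = r[col]
            kwargs[name] = None if pd.isna(v) else float(v)
        out.append(SoilSample(**kwargs))
    return out
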