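"""Tabular readers and writers.

All tables are UTF-8 delimited text (comma or tab, auto-detected) with a
header row and decimal points. Validation is total: every malformed row
produces a row-addressed message and the whole read fails with a
:class:`TableValidationError` listing them all.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    EffortRecord,
    FishRecord,
    GearClass,
    Habitat,
    IsotopeSample,
    Maturity,
    Month,
    PREY_CATEGORIES,
    Species,
    TableValidationError,
    ValidationError,
)

__all__ = [
    "read_fish_table",
    "read_effort_table",
    "read_isotope_table",
    "write_report",
    "fish_to_frame",
    "effort_to_frame",
    "isotopes_to_frame",
]

#: fixed (non-taxon) fish-table columns
_FISH_FIXED = {
    "fish_id",
    "species",
    "habitat",
    "month",
    "year",
    "gear_class",
    "total_length",
    "weight",
    "maturity",
    "total_fullness",
}

# full precision so that write -> read round trips are exact
_FLOAT_FORMAT = "%.17g"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; python engine required for sniffing
    return pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)


def _opt_float(value: object) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return math.nan
    return None if math.isnan(v) else v


def read_fish_table(path: str | Path, mapping: Mapping[str, str]) -> list[FishRecord]:
    """Read a fish table, aggregating taxon columns into the six prey
    categories through ``mapping`` (taxon name -> category name).

    Raises :class:`TableValidationError` naming every offending row, and
    :class:`ValidationError` for an unmapped taxon column.
    """
    df = _read_delimited(path)
    missing = {"fish_id", "species", "habitat", "month", "year", "total_length", "total_fullness"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")

    lower_map = {str(k).lower(): v for k, v in mapping.items()}
    taxon_cols: dict[str, str] = {}
    for col in df.columns:
        if col in _FISH_FIXED:
            continue
        cat = lower_map.get(col.lower())
        if cat is None:
            raise ValidationError(f"{path}: unmapped taxon column {col!r}")
        if cat not in PREY_CATEGORIES:
            raise ValidationError(f"{path}: taxon column {col!r} maps to unknown category {cat!r}")
        taxon_cols[col] = cat

    records: list[FishRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        try:
            by_prey: dict[str, float] = {}
            for col, cat in taxon_cols.items():
                v = row[col]
                v = 0.0 if pd.isna(v) else float(v)
                by_prey[cat] = by_prey.get(cat, 0.0) + v
            weight = row.get("weight")
            records.append(
                FishRecord(
                    fish_id=str(row["fish_id"]),
                    species=Species.parse(row["species"]),
                    habitat=Habitat.parse(row["habitat"]),
                    month=Month.parse(row["month"]),
                    year=int(row["year"]),
                    total_length=float(row["total_length"]),
                    weight=None if weight is None or pd.isna(weight) else float(weight),
                    stomach_total_fullness=float(row["total_fullness"]),
                    fullness_by_prey=by_prey,
                    maturity=Maturity.parse(row.get("maturity", "unknown")) if not pd.isna(row.get("maturity", "unknown")) else Maturity.UNKNOWN,
                    gear_class=GearClass.parse(row.get("gear_class", "survey")) if not pd.isna(row.get("gear_class", "survey")) else GearClass.SURVEY,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise TableValidationError(str(path), errors)
    return records


def read_effort_table(path: str | Path) -> list[EffortRecord]:
    df = _read_delimited(path)
    missing = {"habitat", "month", "year", "net_area", "nights"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    records: list[EffortRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rowno = idx + 2
        try:
            records.append(
                EffortRecord(
                    habitat=Habitat.parse(row["habitat"]),
                    month=Month.parse(row["month"]),
                    year=int(row["year"]),
                    net_area=float(row["net_area"]),
                    nights=int(row["nights"]),
                    gear_class=GearClass.parse(row.get("gear_class", "survey")) if not pd.isna(row.get("gear_class", "survey")) else GearClass.SURVEY,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise TableValidationError(str(path), errors)
    return records


def read_isotope_table(path: str | Path) -> list[IsotopeSample]:
    """Read an isotope table; %C/%N are required by the
    concentration-dependent mixing model, so missing values are errors."""
    df = _read_delimited(path)
    missing = {"group", "d13C", "d15N", "pct_C", "pct_N"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    samples: list[IsotopeSample] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rowno = idx + 2
        try:
            for col in ("d13C", "d15N", "pct_C", "pct_N"):
                if pd.isna(row[col]):
                    raise ValidationError(f"missing {col}")
            habitat = row.get("habitat")
            samples.append(
                IsotopeSample(
                    sample_id=str(row.get("sample_id", f"s{rowno}")),
                    group=str(row["group"]),
                    d13C=float(row["d13C"]),
                    d15N=float(row["d15N"]),
                    pct_C=float(row["pct_C"]),
                    pct_N=float(row["pct_N"]),
                    habitat=None if habitat is None or pd.isna(habitat) else Habitat.parse(habitat),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise TableValidationError(str(path), errors)
    return samples


# ----------------------------------------------------------------------
# frames (for writing / simulation output)

def fish_to_frame(records: Iterable[FishRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "fish_id": r.fish_id,
            "species": r.species.value,
            "habitat": r.habitat.value,
            "month": r.month.value,
            "year": r.year,
            "gear_class": r.gear_class.value,
            "total_length": r.total_length,
            "weight": r.weight,
            "maturity": r.maturity.value,
            "total_fullness": r.stomach_total_fullness,
        }
        for cat, v in zip(PREY_CATEGORIES, r.fullness_vector()):
            row[cat] = v
        rows.append(row)
    cols = ["fish_id", "species", "habitat", "month", "year", "gear_class", "total_length", "weight", "maturity", "total_fullness", *PREY_CATEGORIES]
    return pd.DataFrame(rows, columns=cols)


def effort_to_frame(records: Iterable[EffortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "habitat": r.habitat.value,
                "month": r.month.value,
                "year": r.year,
                "net_area": r.net_area,
                "nights": r.nights,
                "gear_class": r.gear_class.value,
            }
            for r in records
        ],
        columns=["habitat", "month", "year", "net_area", "nights", "gear_class"],
    )


def isotopes_to_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "habitat": s.habitat.value if s.habitat is not None else "",
                "d13C": s.d13C,
                "d15N": s.d15N,
                "pct_C": s.pct_C,
                "pct_N": s.pct_N,
            }
            for s in samples
        ],
        columns=["sample_id", "group", "habitat", "d13C", "d15N", "pct_C", "pct_N"],
    )


# ----------------------------------------------------------------------
# reports

def _to_frame(results: object) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    to_df = getattr(results, "to_dataframe", None)
    if callable(to_df):
        return to_df()
    if isinstance(results, (list, tuple)) and all(dataclasses.is_dataclass(r) for r in results):
        return pd.DataFrame([dataclasses.asdict(r) for r in results])
    raise TypeError(f"cannot serialize object of type {type(results).__name__} as a table")


def _jsonify(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return getattr(obj, "value")
    return obj


def write_report(results: object, path: str | Path, format: str = "tsv") -> Path:
    """Serialize a stage result deterministically as TSV or JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = _to_frame(results)
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    elif format == "json":
        path.write_text(json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")
    return path
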