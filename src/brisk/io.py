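"""File formats: hazard tables, parameter YAML, cohort CSVs, reports.

All risk values are carried as fractions in [0, 1] internally; percent
formatting happens only at presentation time.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .risk_engine import (
    BmiParams,
    BmiStratum,
    DensityCategory,
    DensityParams,
    FamilyHistoryBand,
    FamilyHistoryTable,
    HazardTable,
    RelativeRiskParameterSet,
    RiskFactorProfile,
)
from .validation import ScoredSubject

__all__ = [
    "load_hazard_csv",
    "save_hazard_csv",
    "load_parameter_yaml",
    "read_cohort_csv",
    "read_scored_csv",
    "file_digest",
]

COHORT_COLUMNS = (
    "id",
    "age",
    "n_fdr",
    "age_youngest_fdr",
    "n_sdr",
    "percent_density",
    "density_category",
    "bmi",
    "menopausal_status",
    "prs",
)


def load_hazard_csv(path: str) -> HazardTable:
    """Read an ``age,incidence,mortality`` CSV (rates per woman-year)."""
    df = pd.read_csv(path)
    required = {"age", "incidence", "mortality"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: hazard table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    try:
        return HazardTable(df["age"].to_numpy(), df["incidence"].to_numpy(), df["mortality"].to_numpy())
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def save_hazard_csv(hazards: HazardTable, path: str) -> None:
    ages = np.arange(hazards.age_min, hazards.age_max + 1)
    h1, h2 = hazards.slice_arrays(hazards.age_min, hazards.age_max + 1)
    pd.DataFrame({"age": ages, "incidence": h1, "mortality": h2}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter YAML
# ---------------------------------------------------------------------------


def _require(mapping: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"{where}: missing required key {key!r}")
    return mapping[key]


def _range_pair(value: Any, where: str) -> tuple[Any, Any]:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ConfigurationError(f"{where}: expected a [min, max] pair, got {value!r}")
    return value[0], value[1]


def load_parameter_yaml(path: str) -> RelativeRiskParameterSet:
    """Read a relative-risk parameter set from a YAML config.

    Top-level keys ``family_history``, ``density``, ``bmi`` (each optional;
    omitting one disables the component) and optional ``rr_cap``.  Density
    requires an explicit ``mode: continuous|categorical``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: parameter file must be a mapping")
    unknown = set(doc) - {"family_history", "density", "bmi", "rr_cap"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level keys {sorted(unknown)}")

    fh_table = None
    if "family_history" in doc and doc["family_history"] is not None:
        where = f"{path}: family_history"
        bands_doc = _require(doc["family_history"], "bands", where)
        bands = []
        for i, b in enumerate(bands_doc):
            bw = f"{where}.bands[{i}]"
            kwargs: dict[str, Any] = {
                "name": _require(b, "name", bw),
                "rr": float(_require(b, "rr", bw)),
                "weight": float(_require(b, "weight", bw)),
            }
            if "n_fdr" in b:
                lo, hi = _range_pair(b["n_fdr"], bw)
                kwargs["n_fdr_min"] = int(lo or 0)
                kwargs["n_fdr_max"] = None if hi is None else int(hi)
            if "n_sdr" in b:
                lo, hi = _range_pair(b["n_sdr"], bw)
                kwargs["n_sdr_min"] = int(lo or 0)
                kwargs["n_sdr_max"] = None if hi is None else int(hi)
            if "dx_age" in b:
                lo, hi = _range_pair(b["dx_age"], bw)
                kwargs["dx_age_min"] = None if lo is None else float(lo)
                kwargs["dx_age_max"] = None if hi is None else float(hi)
            bands.append(FamilyHistoryBand(**kwargs))
        try:
            fh_table = FamilyHistoryTable(bands=tuple(bands))
        except ConfigurationError as exc:
            raise ConfigurationError(f"{where}: {exc}") from exc

    density = None
    if "density" in doc and doc["density"] is not None:
        where = f"{path}: density"
        d = doc["density"]
        mode = _require(d, "mode", where)
        try:
            if mode == "continuous":
                density = DensityParams(
                    mode="continuous",
                    slope=float(_require(d, "slope", where)),
                    reference=float(_require(d, "reference", where)),
                )
            elif mode == "categorical":
                cats = [
                    DensityCategory(
                        name=_require(c, "name", f"{where}.categories[{i}]"),
                        rr=float(_require(c, "rr", f"{where}.categories[{i}]")),
                        weight=float(_require(c, "weight", f"{where}.categories[{i}]")),
                        upper=None if c.get("upper") is None else float(c["upper"]),
                    )
                    for i, c in enumerate(_require(d, "categories", where))
                ]
                density = DensityParams(mode="categorical", categories=tuple(cats))
            else:
                raise ConfigurationError(f"mode must be continuous|categorical, got {mode!r}")
        except ConfigurationError as exc:
            raise ConfigurationError(f"{where}: {exc}") from exc

    bmi = None
    if "bmi" in doc and doc["bmi"] is not None:
        where = f"{path}: bmi"
        strata = {}
        for stratum in ("pre", "post"):
            s = _require(doc["bmi"], stratum, where)
            strata[stratum] = BmiStratum(
                slope=float(_require(s, "slope", f"{where}.{stratum}")),
                reference=float(_require(s, "reference", f"{where}.{stratum}")),
            )
        bmi = BmiParams(**strata)

    rr_cap = doc.get("rr_cap")
    return RelativeRiskParameterSet(
        fh_table=fh_table,
        density_params=density,
        bmi_params=bmi,
        rr_cap=None if rr_cap is None else float(rr_cap),
    )


# ---------------------------------------------------------------------------
# Cohort CSVs
# ---------------------------------------------------------------------------


def _opt(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_cohort_csv(path: str) -> tuple[pd.DataFrame, list[RiskFactorProfile]]:
    """Read a per-woman cohort CSV into profiles.

    Required columns: ``id``, ``age``; the remaining model inputs are
    optional and missing cells become absent fields.  The raw frame is
    returned alongside so extra columns (status, precomputed competing-model
    scores) survive a score round trip.
    """
    df = pd.read_csv(path)
    for col in ("id", "age"):
        if col not in df.columns:
            raise InputError(f"{path}: cohort is missing required column {col!r}")
    profiles = []
    for i, row in df.iterrows():
        status = row.get("menopausal_status")
        if isinstance(status, float) and math.isnan(status):
            status = None
        cat = _opt(row.get("density_category"))
        profiles.append(
            RiskFactorProfile(
                age=float(row["age"]),
                n_fdr=int(row.get("n_fdr", 0) or 0),
                age_youngest_fdr=_opt(row.get("age_youngest_fdr")),
                n_sdr=int(row.get("n_sdr", 0) or 0),
                percent_density=_opt(row.get("percent_density")),
                density_category=None if cat is None else int(cat),
                bmi=_opt(row.get("bmi")),
                menopausal_status=status,
                prs=_opt(row.get("prs")),
            )
        )
    return df, profiles


def read_scored_csv(path: str) -> list[ScoredSubject]:
    """Read a scored cohort (``id``, ``status``, ``age`` plus ``score_*``
    columns and optional ``er``/``pr``/``stage`` subgroup labels)."""
    df = pd.read_csv(path)
    for col in ("id", "status", "age"):
        if col not in df.columns:
            raise InputError(f"{path}: scored cohort missing column {col!r}")
    score_cols = [c for c in df.columns if c.startswith("score_")]
    if not score_cols:
        raise InputError(f"{path}: no score_* columns found")
    subgroup_cols = [c for c in ("er", "pr", "stage") if c in df.columns]
    subjects = []
    for i, row in df.iterrows():
        status = str(row["status"]).lower()
        if status not in ("case", "control"):
            raise InputError(f"{path} row {i}: status must be case|control, got {status!r}")
        scores = {}
        for c in score_cols:
            v = _opt(row[c])
            if v is not None:
                if not 0.0 <= v <= 1.0:
                    raise InputError(f"{path} row {i}: {c} = {v} outside [0, 1]")
                scores[c.removeprefix("score_")] = v
        subgroups = {}
        for c in subgroup_cols:
            v = row[c]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                subgroups[c] = str(v)
        subjects.append(
            ScoredSubject(
                id=str(row["id"]),
                is_case=status == "case",
                age=float(row["age"]),
                scores=scores,
                subgroups=subgroups,
            )
        )
    return subjects


def file_digest(*paths_and_blobs: str) -> str:
    """Stable hex digest over input file contents and option strings."""
    h = hashlib.sha256()
    for item in paths_and_blobs:
        try:
            with open(item, "rb") as fh:
                h.update(fh.read())
        except (OSError, ValueError):
            h.update(str(item).encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]
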