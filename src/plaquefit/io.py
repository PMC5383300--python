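"""File formats: cohort/dose CSVs and the YAML run configuration.

Cohort CSV (one row per worker):
    id, birth_year, age_in, age_out, event, smoking, blood_pressure,
    graduation
Dose CSV (long format, one row per worker-year with non-zero dose):
    id, calendar_year, dose_gy

Ages are decimal years (calendar linkage through birth_year); doses in Gy.
Configuration files are YAML with per-section keys; unknown keys are errors
so that a typo in a rate name cannot be silently ignored.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from .likelihood import CATEGORIES, Cohort, WorkerRecord
from .params import (AgePowerLaw, CovariateModifier, DoseResponse, RateSet)

__all__ = ["read_cohort", "write_cohort", "load_config", "parse_rates",
           "config_hash"]

COHORT_COLUMNS = ["id", "birth_year", "age_in", "age_out", "event",
                  "smoking", "blood_pressure", "graduation"]
DOSE_COLUMNS = ["id", "calendar_year", "dose_gy"]


class SchemaError(ValueError):
    """A CSV or config file violates its documented schema."""


def read_cohort(cohort_csv, dose_csv=None) -> Cohort:
    """Load and validate worker records; workers absent from the dose file
    get zero-dose histories, dose rows without a worker are errors."""
    df = pd.read_csv(cohort_csv, dtype={"id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort CSV lacks columns {sorted(missing)}")
    doses: Dict[str, list] = {}
    if dose_csv is not None:
        dd = pd.read_csv(dose_csv, dtype={"id": str})
        dmissing = set(DOSE_COLUMNS) - set(dd.columns)
        if dmissing:
            raise SchemaError(f"dose CSV lacks columns {sorted(dmissing)}")
        known = set(df["id"])
        orphan = set(dd["id"]) - known
        if orphan:
            raise SchemaError(
                f"dose rows for unknown workers: {sorted(orphan)[:5]}")
        if (dd["dose_gy"] < 0).any():
            raise SchemaError("negative doses in dose CSV")
        for row in dd.itertuples(index=False):
            doses.setdefault(row.id, []).append(
                (int(row.calendar_year), float(row.dose_gy)))
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(WorkerRecord(
                id=row.id, birth_year=int(row.birth_year),
                age_in=float(row.age_in), age_out=float(row.age_out),
                event=int(row.event), smoking=row.smoking,
                blood_pressure=row.blood_pressure, graduation=row.graduation,
                dose_history=tuple(sorted(doses.get(row.id, [])))))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"cohort CSV row {i + 2}: {exc}") from exc
    return Cohort(records)


def write_cohort(cohort: Cohort, cohort_csv, dose_csv=None) -> None:
    cdf, ddf = cohort.to_dataframes()
    cdf.to_csv(cohort_csv, index=False)
    if dose_csv is not None:
        ddf.to_csv(dose_csv, index=False)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

_KNOWN_SECTIONS = {"rates", "age_laws", "modifiers", "dose_response",
                   "simulation", "fit", "empirical", "profile"}
_RATE_KEYS = {"nu0N", "alpha", "gamma", "nu1", "nu2", "t_lag"}


def load_config(path) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")
    if "rates" in cfg:
        bad = set(cfg["rates"]) - _RATE_KEYS
        if bad:
            raise SchemaError(f"unknown rate names: {sorted(bad)}")
    return cfg


def parse_rates(cfg: Dict) -> Tuple[RateSet, tuple, tuple,
                                    Optional[DoseResponse]]:
    """(base rates, age laws, covariate modifiers, dose response)."""
    if "rates" not in cfg:
        raise SchemaError("config lacks a 'rates' section")
    rates = RateSet(**cfg["rates"])
    laws = tuple(AgePowerLaw(**law) for law in cfg.get("age_laws", []))
    mods = tuple(CovariateModifier(**m) for m in cfg.get("modifiers", []))
    dr = (DoseResponse(**cfg["dose_response"])
          if cfg.get("dose_response") else None)
    for m in mods:
        for cat in m.multipliers:
            if cat not in CATEGORIES[m.covariate_name]:
                raise SchemaError(
                    f"unknown category {cat!r} for {m.covariate_name}")
    return rates, laws, mods, dr


def config_hash(cfg: Dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
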