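"""Readers, writers and the JSON report for the louse-population pipeline.

File formats are deliberately plain: host counts as two-column CSV
(``host_id,count``), stage schedules as YAML/JSON mappings, life tables as
three-column CSV (``x,lx,mx``), and analysis results as a single JSON
report validated against the versioned schema shipped with the package.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import (
    AggregationSummary,
    DiscrepancyIndex,
    GOFResult,
    HostCounts,
    NegBinFit,
)
from .demography import (
    STAGE_NAMES,
    DemographyResult,
    Duration,
    LifeTable,
    Stage,
    StageSchedule,
)
from .synthetic import RearingRecord

__all__ = [
    "read_host_counts",
    "write_host_counts",
    "read_stage_schedule",
    "write_stage_schedule",
    "schedule_to_dict",
    "schedule_from_dict",
    "read_life_table",
    "write_life_table",
    "write_rearing_cohort",
    "aggregation_block",
    "demography_block",
    "assemble_report",
    "write_report",
    "validate_report",
    "file_digest",
]

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------- host counts

def read_host_counts(path: str | Path) -> HostCounts:
    """Read a ``host_id,count`` CSV into :class:`HostCounts`.

    Errors name the offending row and column so malformed tables are easy
    to fix.
    """
    df = pd.read_csv(path, dtype={"host_id": str})
    for col in ("host_id", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    counts = []
    for row_number, value in enumerate(df["count"], start=2):  # 1 = header line
        try:
            as_float = float(value)
            if not as_float.is_integer() or as_float < 0:
                raise ValueError
            counts.append(int(as_float))
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {row_number}, column 'count': {value!r} is not "
                "a non-negative integer"
            ) from None
    return HostCounts(np.array(counts, dtype=np.int64), tuple(df["host_id"]))


def write_host_counts(counts: HostCounts, path: str | Path) -> None:
    ids = counts.host_ids or tuple(
        f"host{i + 1:03d}" for i in range(counts.n_hosts)
    )
    pd.DataFrame({"host_id": ids, "count": counts.counts}).to_csv(path, index=False)


# ------------------------------------------------------------ stage schedules

def _duration_from(obj: Mapping[str, Any], where: str, problems: list[str]) -> Optional[Duration]:
    missing = [k for k in ("mean", "sd", "min", "max") if k not in obj]
    if missing:
        problems.append(f"{where}: missing key(s) {missing}")
        return None
    try:
        return Duration(float(obj["mean"]), float(obj["sd"]),
                        float(obj["min"]), float(obj["max"]))
    except (TypeError, ValueError) as exc:
        problems.append(f"{where}: {exc}")
        return None


def schedule_from_dict(data: Mapping[str, Any]) -> StageSchedule:
    """Build a :class:`StageSchedule` from a plain mapping, enumerating every
    validation problem instead of stopping at the first."""
    problems: list[str] = []
    stages: list[Stage] = []
    raw_stages = data.get("stages")
    if not isinstance(raw_stages, list) or not raw_stages:
        problems.append("'stages' must be a non-empty list")
    else:
        for i, st in enumerate(raw_stages):
            name = st.get("name") if isinstance(st, Mapping) else None
            if not name:
                problems.append(f"stages[{i}]: missing 'name'")
                continue
            dur = _duration_from(st, f"stages[{i}] ({name})", problems)
            if dur is not None:
                stages.append(Stage(str(name), dur))
    lifespans = {}
    for key in ("adult_female_lifespan", "adult_male_lifespan"):
        obj = data.get(key)
        if not isinstance(obj, Mapping):
            problems.append(f"'{key}' must be a mapping with mean/sd/min/max")
        else:
            d = _duration_from(obj, key, problems)
            if d is not None:
                lifespans[key] = d
    scalars = {}
    for key, lo, hi in (
        ("eggs_per_female_day", 0.0, math.inf),
        ("lifetime_eggs_per_female", 0.0, math.inf),
        ("female_fraction", 0.0, 1.0),
    ):
        val = data.get(key)
        try:
            val = float(val)
            if not lo <= val <= hi or (key == "female_fraction" and not 0 < val < 1):
                raise ValueError
            scalars[key] = val
        except (TypeError, ValueError):
            problems.append(f"'{key}' must be a number in ({lo}, {hi})")
    survival = data.get("stage_survival", {name: 1.0 for name in STAGE_NAMES})
    if not isinstance(survival, Mapping):
        problems.append("'stage_survival' must map stage name -> probability")
        survival = {}
    if problems:
        raise ValueError(
            "invalid stage schedule:\n  - " + "\n  - ".join(problems)
        )
    return StageSchedule(
        stages=tuple(stages),
        adult_female_lifespan=lifespans["adult_female_lifespan"],
        adult_male_lifespan=lifespans["adult_male_lifespan"],
        stage_survival=dict(survival),
        **scalars,
    )


def schedule_to_dict(schedule: StageSchedule) -> dict[str, Any]:
    def dur(d: Duration) -> dict[str, float]:
        return {"mean": d.mean, "sd": d.sd, "min": d.min_days, "max": d.max_days}

    return {
        "stages": [{"name": st.name, **dur(st.duration)} for st in schedule.stages],
        "adult_female_lifespan": dur(schedule.adult_female_lifespan),
        "adult_male_lifespan": dur(schedule.adult_male_lifespan),
        "eggs_per_female_day": schedule.eggs_per_female_day,
        "lifetime_eggs_per_female": schedule.lifetime_eggs_per_female,
        "female_fraction": schedule.female_fraction,
        "stage_survival": dict(schedule.stage_survival),
    }


def read_stage_schedule(path: str | Path) -> StageSchedule:
    """Read a stage schedule from YAML (or JSON — a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: schedule file must contain a mapping")
    return schedule_from_dict(data)


def write_stage_schedule(schedule: StageSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


# ------------------------------------------------------------ life tables

def read_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    for col in ("x", "lx", "mx"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return LifeTable(
        x=df["x"].to_numpy(float),
        lx=df["lx"].to_numpy(float),
        mx=df["mx"].to_numpy(float),
    )


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"x": lt.x, "lx": lt.lx, "mx": lt.mx}).to_csv(path, index=False)


def write_rearing_cohort(records: Sequence[RearingRecord], path: str | Path) -> None:
    """Flat CSV, one row per individual."""
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "individual_id": r.individual_id,
            "sex": r.sex,
            "died_in_stage": r.died_in_stage or "",
            "adult_lifespan": r.adult_lifespan if r.adult_lifespan is not None else "",
            "eggs_laid": r.eggs_laid,
            "death_age": r.death_age,
        }
        for name in STAGE_NAMES:
            row[name] = r.stage_durations.get(name, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------ JSON report

def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _round(v: Optional[float], nd: int = 2) -> Optional[float]:
    return None if v is None else round(v, nd)


def aggregation_block(
    summary: AggregationSummary,
    fit_moments: Optional[NegBinFit],
    fit_mle: Optional[NegBinFit],
    discrepancy: DiscrepancyIndex,
    gof: Optional[GOFResult],
) -> dict[str, Any]:
    """Assemble the 'aggregation' half of a report.

    The moment fit and the goodness-of-fit test may be unavailable (no
    overdispersion, too few classes); they appear as null with a reason
    rather than vanishing.
    """

    def fit_dict(fit: Optional[NegBinFit]) -> Optional[dict[str, Any]]:
        return None if fit is None else asdict(fit)

    block: dict[str, Any] = {
        "summary": asdict(summary),
        "negbin": {"moments": fit_dict(fit_moments), "mle": fit_dict(fit_mle)},
        "discrepancy": {"D": discrepancy.D},
        "gof": None
        if gof is None
        else {
            "chi2": gof.chi2,
            "df": gof.df,
            "p_value": gof.p_value,
            "classes": [list(c) for c in gof.classes],
        },
    }
    block["display"] = {
        "prevalence_pct": _round(summary.prevalence * 100, 1),
        "mean_intensity": _round(summary.mean_intensity, 1),
        "mean_abundance": _round(summary.mean_abundance, 1),
        "variance_to_mean": _round(summary.variance_to_mean, 2),
        "k_mle": _round(fit_mle.k, 3) if fit_mle else None,
        "k_moments": _round(fit_moments.k, 3) if fit_moments else None,
        "D": _round(discrepancy.D, 3),
        "chi2": _round(gof.chi2, 2) if gof else None,
        "p_value": _round(gof.p_value, 3) if gof else None,
    }
    return block


def demography_block(result: DemographyResult, lt: LifeTable) -> dict[str, Any]:
    return {
        "R0": result.R0,
        "rm": result.rm,
        "T": result.T,
        "DT": result.DT,
        "lambda": result.lam,
        "n_age_classes": int(lt.x.size),
        "display": {
            "R0": _round(result.R0, 2),
            "rm": _round(result.rm, 4),
            "T_days": _round(result.T, 2),
            "DT_days": _round(result.DT, 2),
            "lambda": _round(result.lam, 4),
        },
    }


def assemble_report(
    *,
    command: str,
    config: Mapping[str, Any],
    seed: Optional[int],
    timestamp: str,
    aggregation: Optional[Mapping[str, Any]] = None,
    demography: Optional[Mapping[str, Any]] = None,
    inputs: Optional[Mapping[str, str]] = None,
) -> dict[str, Any]:
    """One versioned JSON document for a pipeline run.

    The timestamp is isolated in a single field so the remainder of the
    report is byte-reproducible for identical inputs and configuration.
    """
    report = {
        "schema_version": SCHEMA_VERSION,
        "tool": {"name": "lousepop", "version": __version__},
        "command": command,
        "seed": seed,
        "config": dict(config),
        "inputs": dict(inputs or {}),
        "timestamp": timestamp,
        "aggregation": dict(aggregation) if aggregation is not None else None,
        "demography": dict(demography) if demography is not None else None,
    }
    validate_report(report)
    return report


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")


# ------------------------------------------------------- schema validation

def _load_schema() -> dict[str, Any]:
    text = resources.files("lousepop").joinpath(
        f"schemas/report-v{SCHEMA_VERSION}.json"
    ).read_text()
    return json.loads(text)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check(node: Any, schema: Mapping[str, Any], where: str, errors: list[str]) -> None:
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if not any(isinstance(node, _TYPES[t]) and not
                   (t in ("integer", "number") and isinstance(node, bool))
                   for t in types):
            errors.append(f"{where}: expected {types}, got {type(node).__name__}")
            return
    if isinstance(node, dict):
        for req in schema.get("required", []):
            if req not in node:
                errors.append(f"{where}: missing required key '{req}'")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{where}.{key}", errors)


def validate_report(report: Mapping[str, Any]) -> None:
    """Validate a report against the shipped versioned schema.

    Raises ``ValueError`` listing every violation.  (Implements the small
    structural subset of JSON Schema the report format needs: type,
    required, properties.)
    """
    errors: list[str] = []
    _check(dict(report), _load_schema(), "report", errors)
    if errors:
        raise ValueError("report schema violations:\n  - " + "\n  - ".join(errors))
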