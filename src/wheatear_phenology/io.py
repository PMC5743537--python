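"""Readers, writers and configuration for the analysis pipeline.

Input formats
-------------
Climate CSV: ``date`` (ISO-8601), ``tmean_c``, ``precip_mm``; one row per
day, header required.

Breeding CSV: one row per nest attempt with the canonical schema of
:data:`wheatear_phenology.matching.BREEDING_COLUMNS`.  Nestling weights
live in a separate long-format CSV keyed by ``nest_id`` with columns
``nestling_age`` and ``weight``.

Row-level invariant violations (recruits exceeding fledglings, hatch before
lay, rain days outside 0–16) reject the offending rows and are reported
with line numbers; schema violations are fatal.

Every output CSV starts with a provenance comment line carrying the run
seed and configuration hash, so no table exists without provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from wheatear_phenology.matching import BREEDING_COLUMNS, NESTLING_PERIOD_DAYS
from wheatear_phenology.thermal import ClimateSeries

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "RowReport",
    "read_climate_csv",
    "read_breeding_csv",
    "read_nestling_csv",
    "write_table",
    "config_hash",
]

log = logging.getLogger("wheatear")


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


@dataclass
class RowReport:
    """Per-file record of rejected rows (1-based data line numbers)."""

    path: str
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line: int, reason: str) -> None:
        self.rejected.append((line, reason))

    def __len__(self) -> int:
        return len(self.rejected)


@dataclass
class PipelineConfig:
    """Run configuration for the full pipeline."""

    climate_csv: str = ""
    breeding_csv: str = ""
    nestling_csv: str = ""
    out_dir: str = "results"
    t_base_grid: tuple[float, ...] = tuple(range(-5, 11))
    threshold_step: float = 100.0
    matching_t_base: float | None = None  # None: use the winning indicator's base
    weight_rule: str = "inv_se"  # paper-faithful 1/SE; "inv_var" for sensitivity
    bootstrap_n: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "t_base_grid" in raw:
            raw["t_base_grid"] = tuple(raw["t_base_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t_base_grid"] = list(self.t_base_grid)
        return d


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (output location and verbosity excluded)."""
    payload = {k: v for k, v in config.to_dict().items() if k not in ("out_dir", "log_level")}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def read_climate_csv(path: str | Path) -> ClimateSeries:
    """Load and validate a daily climate series."""
    df = pd.read_csv(path, comment="#")
    required = ["date", "tmean_c", "precip_mm"]
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing:
        raise SchemaError(f"{path}: missing climate columns {missing}" + (f", extra {extra}" if extra else ""))
    if len(df) == 0:
        raise SchemaError(f"{path}: empty climate file")
    series = ClimateSeries(df)
    log.info("stage=read_climate file=%s rows_in=%d days_out=%d", path, len(df), len(series.frame))
    return series


def read_breeding_csv(path: str | Path) -> tuple[pd.DataFrame, RowReport]:
    """Load the breeding-record table, rejecting invariant-violating rows."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BREEDING_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in BREEDING_COLUMNS]
    if missing or extra:
        raise SchemaError(f"{path}: breeding schema mismatch: missing {missing}, extra {extra}")
    df["lay_date"] = pd.to_datetime(df["lay_date"]).dt.date
    df["hatch_date"] = pd.to_datetime(df["hatch_date"], errors="coerce").dt.date

    report = RowReport(path=str(path))
    keep = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 1
        if row["n_recruits"] > row["n_fledglings"]:
            report.add(line, f"nest {row['nest_id']}: recruits ({row['n_recruits']}) > fledglings ({row['n_fledglings']})")
        elif pd.notna(row["hatch_date"]) and row["hatch_date"] <= row["lay_date"]:
            report.add(line, f"nest {row['nest_id']}: hatch date not after lay date")
        elif not 0 <= row["rain_days"] <= NESTLING_PERIOD_DAYS:
            report.add(line, f"nest {row['nest_id']}: rain_days {row['rain_days']} outside [0, {NESTLING_PERIOD_DAYS}]")
        else:
            keep.append(pos)
    clean = df.iloc[keep].reset_index(drop=True)
    for line, reason in report.rejected:
        log.warning("stage=read_breeding file=%s line=%d rejected: %s", path, line, reason)
    log.info("stage=read_breeding file=%s rows_in=%d rows_out=%d rejected=%d", path, len(df), len(clean), len(report))
    return clean, report


def read_nestling_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = ["nest_id", "nestling_age", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing nestling columns {missing}")
    log.info("stage=read_nestlings file=%s rows=%d", path, len(df))
    return df


def write_table(df: pd.DataFrame, path: str | Path, seed: int, cfg_hash: str, **fmt) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# provenance: seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, **fmt)
    log.info("stage=write file=%s rows=%d", path, len(df))
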