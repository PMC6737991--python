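"""File round-tripping: interview tables, config files, result tables.

Flat tables are comma-separated with a fixed column order and a
metadata header of ``#``-prefixed lines (tool version, seed, config
hash) so any output can be re-run exactly. Structured configuration is
YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import EngineConfig
from .interview import FarmerInterview

logger = logging.getLogger("ricessnm")

#: Canonical column order for interview tables; names match the
#: FarmerInterview fields exactly.
INTERVIEW_COLUMNS = [
    "field_id", "district", "acz", "season", "year", "water_regime",
    "variety_name", "growth_duration_days", "seedling_age_days",
    "transplant_delay_days", "historical_yield_GYR", "variety_yield_ceiling",
    "previous_crop_yield", "residue_retained_fraction", "selected_products",
    "farmer_applies_zinc",
]

MANDATORY_COLUMNS = [
    "field_id", "season", "growth_duration_days", "seedling_age_days",
    "historical_yield_GYR",
]

NUMERIC_COLUMNS = [
    "growth_duration_days", "seedling_age_days", "transplant_delay_days",
    "historical_yield_GYR", "variety_yield_ceiling", "previous_crop_yield",
    "residue_retained_fraction",
]


class SchemaError(ValueError):
    """Input table is missing a mandatory column or has a bad value."""


def config_hash(cfg: EngineConfig) -> str:
    """Short stable digest of an engine configuration."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def metadata_header(
    seed: Optional[int] = None, cfg: Optional[EngineConfig] = None
) -> list[str]:
    lines = [f"# ricessnm {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg is not None:
        lines.append(f"# config_hash: {config_hash(cfg)}")
    return lines


def write_table(
    path: str | Path,
    frame: pd.DataFrame,
    seed: Optional[int] = None,
    cfg: Optional[EngineConfig] = None,
) -> None:
    """Write a flat table with the metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for line in metadata_header(seed, cfg):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def interviews_to_frame(interviews: Sequence[FarmerInterview]) -> pd.DataFrame:
    rows = []
    for iv in interviews:
        d = iv.model_dump()
        d["season"] = iv.season.value
        d["water_regime"] = iv.water_regime.value
        d["selected_products"] = ";".join(iv.selected_products)
        rows.append(d)
    return pd.DataFrame(rows, columns=INTERVIEW_COLUMNS)


def frame_to_interviews(frame: pd.DataFrame, source: str = "<frame>") -> list[FarmerInterview]:
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{source}: missing mandatory column {col!r}")
    for col in NUMERIC_COLUMNS:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{source}: malformed numeric value in column {col!r} at row {row}"
            )
    interviews = []
    for idx, row in frame.iterrows():
        kwargs = {
            col: row[col]
            for col in INTERVIEW_COLUMNS
            if col in frame.columns and pd.notna(row[col])
        }
        for col in ("field_id", "district", "acz", "season", "year",
                    "water_regime", "variety_name"):
            if col in kwargs:
                kwargs[col] = str(kwargs[col])
        if "selected_products" in kwargs:
            kwargs["selected_products"] = tuple(
                p for p in str(kwargs["selected_products"]).split(";") if p
            )
        try:
            interviews.append(FarmerInterview(**kwargs))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{source}: invalid record at row {idx}: {exc}") from exc
    return interviews


def write_interviews(path: str | Path, interviews: Sequence[FarmerInterview]) -> None:
    write_table(path, interviews_to_frame(interviews))


def read_interviews(path: str | Path) -> list[FarmerInterview]:
    """Read interviews from a flat table; unknown columns are ignored
    for the records but preserved in the table returned by
    :func:`read_table`."""
    frame = read_table(path)
    if frame.empty:
        logger.warning("no interview records in %s", path)
        return []
    return frame_to_interviews(frame, source=str(path))


def write_recommendations(path: str | Path, frame: pd.DataFrame,
                          seed: Optional[int] = None,
                          cfg: Optional[EngineConfig] = None) -> None:
    write_table(path, frame, seed=seed, cfg=cfg)


def engine_config_to_yaml(cfg: EngineConfig, path: Optional[str | Path] = None) -> str:
    text = yaml.safe_dump(
        json.loads(cfg.model_dump_json()), sort_keys=False, default_flow_style=None
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def engine_config_from_yaml(path: str | Path) -> EngineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return EngineConfig(**(data or {}))
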