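"""Readers, writers, configuration, and the audit record.

Code tables travel as UTF-8 CSV (columns
``code_id,level,specialty,description,points``, header row) or as an
equivalent JSON array of objects.  Parse errors are collected with row
numbers so a whole file can be repaired in one pass.

Money is serialized as decimal strings, never as binary floats, so fee
reports round-trip cent-exactly.  JSON reports use sorted keys and a fixed
separator style: identical inputs produce byte-identical output.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import Decimal
from pathlib import Path
from typing import Any, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .schedule import REGIME_PRESETS, BillingCode, PointValueRegime

__all__ = [
    "CodeTableError",
    "RunConfig",
    "AuditRecord",
    "read_code_table",
    "write_code_table",
    "write_report",
    "load_config",
    "load_regimes",
    "to_jsonable",
    "markdown_table",
]

logger = logging.getLogger("aibilling")

TABLE_COLUMNS = ("code_id", "level", "specialty", "description", "points")

OutputFormat = Literal["json", "csv", "markdown"]


class CodeTableError(ValueError):
    """Raised when a code table cannot be parsed; carries per-row errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class RunConfig(BaseModel):
    """Resolved run configuration with defaults applied."""

    model_config = ConfigDict(frozen=True)

    regimes: dict[str, PointValueRegime] = Field(
        default_factory=lambda: dict(REGIME_PRESETS)
    )
    default_regime: str = "ebm-simplified"
    rounding: Literal["half_up", "half_even"] = "half_up"
    ai_factor_cap: float = 2.0
    default_cohort_size: int = 1000
    seed: Optional[int] = None
    output_format: OutputFormat = "json"


@dataclass(frozen=True)
class AuditRecord:
    """One auditable trace of a command invocation.

    Records what was asked (command and resolved inputs), with what code
    version, and a digest of the output, so any invoice or report can be
    traced back to its inputs.
    """

    command: str
    resolved_inputs: dict
    outputs_digest: str
    package_version: str = field(default="")
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def for_output(cls, command: str, resolved_inputs: dict, output: str) -> "AuditRecord":
        from . import __version__

        digest = hashlib.sha256(output.encode("utf-8")).hexdigest()[:16]
        return cls(
            command=command,
            resolved_inputs=resolved_inputs,
            outputs_digest=digest,
            package_version=__version__,
        )

    def emit(self) -> None:
        """Log the record (one line of JSON) to the package logger."""
        logger.info("audit %s", json.dumps(to_jsonable(self.__dict__), sort_keys=True))


def _rows_to_codes(rows: list[dict], source: str) -> list[BillingCode]:
    codes: list[BillingCode] = []
    errors: list[str] = []
    for i, row in enumerate(rows, start=1):
        missing = [c for c in TABLE_COLUMNS if c not in row or row[c] in (None, "")]
        if missing:
            errors.append(f"{source} row {i}: missing column(s) {missing}")
            continue
        raw_points = row["points"]
        try:
            points = int(str(raw_points).strip())
        except ValueError:
            errors.append(
                f"{source} row {i}: column 'points' is not an integer "
                f"({raw_points!r})"
            )
            continue
        try:
            codes.append(
                BillingCode(
                    code_id=str(row["code_id"]).strip(),
                    level=str(row["level"]).strip(),
                    specialty=str(row["specialty"]).strip(),
                    description=str(row["description"]).strip(),
                    points=points,
                )
            )
        except ValidationError as exc:
            reasons = "; ".join(e["msg"] for e in exc.errors())
            errors.append(f"{source} row {i}: {reasons}")
    if errors:
        raise CodeTableError(errors)
    return codes


def read_code_table(
    path: str | Path, format: Optional[Literal["csv", "json"]] = None
) -> list[BillingCode]:
    """Read a billing-code registry from CSV or JSON.

    The format is inferred from the file extension when not given.  All
    malformed rows are reported together, each with its row number.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        data = json.loads(text)
        if not isinstance(data, list):
            raise CodeTableError([f"{path.name}: expected a JSON array of codes"])
        rows = data
    else:
        reader = csv.DictReader(text.splitlines())
        header = reader.fieldnames or []
        missing = [c for c in TABLE_COLUMNS if c not in header]
        if missing:
            raise CodeTableError([f"{path.name}: missing header column(s) {missing}"])
        rows = list(reader)
    return _rows_to_codes(rows, path.name)


def write_code_table(
    codes: Sequence[BillingCode],
    path: str | Path,
    format: Optional[Literal["csv", "json"]] = None,
) -> None:
    """Write a registry to CSV or JSON (lossless round-trip)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [
        {
            "code_id": c.code_id,
            "level": c.level.value,
            "specialty": c.specialty,
            "description": c.description,
            "points": c.points,
        }
        for c in codes
    ]
    if fmt == "json":
        path.write_text(
            json.dumps(rows, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(TABLE_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)


def to_jsonable(obj: Any) -> Any:
    """Convert results to JSON-safe data; money (Decimal) becomes a string."""
    if isinstance(obj, BaseModel):
        return to_jsonable(obj.model_dump())
    if isinstance(obj, Decimal):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return [to_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def markdown_table(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-style pipe table."""
    headers = [str(c) for c in df.columns]
    rows = [[str(v) for v in rec] for rec in df.itertuples(index=False)]
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    def fmt(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(headers), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines) + "\n"


def write_report(result: Any, format: OutputFormat = "json") -> str:
    """Serialize a result (model, dict, or DataFrame) for output.

    JSON output has sorted keys and is parse/write stable; CSV and markdown
    require tabular input (a DataFrame or list of flat records).
    """
    if format == "json":
        return json.dumps(to_jsonable(result), indent=2, sort_keys=True) + "\n"
    if isinstance(result, pd.DataFrame):
        df = result
    elif isinstance(result, list):
        df = pd.DataFrame([to_jsonable(r) for r in result])
    elif isinstance(result, (dict, BaseModel)):
        flat = to_jsonable(result)
        df = pd.DataFrame([flat])
    else:
        raise ValueError(f"cannot tabulate {type(result).__name__} for {format}")
    df = df.map(lambda v: str(v) if isinstance(v, Decimal) else v)
    if format == "csv":
        return df.to_csv(index=False)
    if format == "markdown":
        return markdown_table(df)
    raise ValueError(f"unsupported format {format!r}")


def load_regimes(raw: list[dict]) -> dict[str, PointValueRegime]:
    """Build regimes from config entries; euro_per_point strings stay exact."""
    regimes = {}
    for entry in raw:
        entry = dict(entry)
        entry["euro_per_point"] = Decimal(str(entry["euro_per_point"]))
        regime = PointValueRegime(**entry)
        regimes[regime.name] = regime
    return regimes


_KNOWN_KEYS = {
    "regimes",
    "default_regime",
    "rounding",
    "ai_factor_cap",
    "default_cohort_size",
    "seed",
    "output_format",
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys.

    Unknown keys produce a warning; an unknown ``default_regime`` reference
    is an error.  Regimes given in the file are merged over the presets.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    for key in sorted(set(raw) - _KNOWN_KEYS):
        logger.warning("config %s: ignoring unknown key %r", path, key)
        raw.pop(key)
    regimes = dict(REGIME_PRESETS)
    if "regimes" in raw:
        regimes.update(load_regimes(raw.pop("regimes")))
    config = RunConfig(regimes=regimes, **raw)
    if config.default_regime not in config.regimes:
        raise ValueError(
            f"config {path}: default_regime {config.default_regime!r} is not "
            f"a defined regime"
        )
    return config
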