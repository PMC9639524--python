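"""Readers and writers for measurement and report tables.

The measurement CSV schema is the package's exchange contract:
``id, group, sex, side, ab_mm, bc_mm, ac_mm`` (UTF-8, decimal point, comma
or tab delimited).  Ingestion validates every row — unparseable lengths,
unknown sex codes, duplicate ids and triangle-inequality violations are
collected in a rejection report with row numbers and reasons, never
silently dropped.  Lengths are kept at full precision; values quoted beyond
2 decimals are flagged (calliper precision is 0.01 mm) but accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geometry import TriangleError, TriangleMeasurements

__all__ = [
    "REQUIRED_COLUMNS",
    "RejectedRow",
    "read_measurements",
    "write_measurements",
    "write_report",
    "record_run_manifest",
]

logger = logging.getLogger("femtri")

REQUIRED_COLUMNS = ("id", "group", "sex", "side", "ab_mm", "bc_mm", "ac_mm")
VALID_SEX = {"M", "F"}


@dataclass(frozen=True)
class RejectedRow:
    row_number: int          # 1-based data-row index in the file
    record_id: str
    reason: str


def _sniff_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_measurements(
    path: str | Path,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, list[RejectedRow]]:
    """Read and validate a measurement CSV.

    Returns the accepted rows (original dtypes: labels as str, lengths as
    float; extra columns preserved) and the list of rejections.  Raises on
    a missing file, an empty file, or missing required columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    accepted_idx: list[int] = []
    rejections: list[RejectedRow] = []
    seen_ids: set[str] = set()
    lengths = {c: [] for c in ("ab_mm", "bc_mm", "ac_mm")}
    for pos, (_, row) in enumerate(raw.iterrows(), start=1):
        rid = row["id"]
        reason = None
        parsed = {}
        if rid in seen_ids:
            reason = f"duplicate id {rid!r}"
        elif row["sex"] not in VALID_SEX:
            reason = f"unknown sex {row['sex']!r} (expected M or F)"
        else:
            for col in ("ab_mm", "bc_mm", "ac_mm"):
                try:
                    parsed[col] = float(row[col])
                except ValueError:
                    reason = f"bad number in {col}: {row[col]!r}"
                    break
        if reason is None:
            try:
                TriangleMeasurements(parsed["ab_mm"], parsed["bc_mm"], parsed["ac_mm"])
            except TriangleError as exc:
                reason = f"triangle inequality: {exc}"
        if reason is None:
            for col, value in parsed.items():
                text = row[col]
                if "." in text and len(text.split(".")[1]) > 2:
                    logger.warning("row %d (%s): %s=%s exceeds 0.01 mm precision",
                                   pos, rid, col, text)
            seen_ids.add(rid)
            accepted_idx.append(pos - 1)
            for col in lengths:
                lengths[col].append(parsed[col])
        else:
            rejections.append(RejectedRow(row_number=pos, record_id=str(rid), reason=reason))

    table = raw.iloc[accepted_idx].reset_index(drop=True)
    for col in ("ab_mm", "bc_mm", "ac_mm"):
        table[col] = lengths[col]
    return table, rejections


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table; round-trips through :func:`read_measurements`."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_report(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any report table (summary, grid, confusion matrix) as CSV.

    Confusion matrices keep their labelled index (pass ``index=True``); an
    empty frame yields a header-only file.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=index)


def record_run_manifest(out_dir: str | Path, seed: int, config: dict) -> Path:
    """Drop a JSON manifest with the seed and a hash of the configuration.

    Every output directory carries this provenance record so any table in it
    can be regenerated.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("run manifest written to %s (seed=%d)", path, seed)
    return path
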