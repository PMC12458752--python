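"""Report data model and tabular readers/writers.

Reports travel as CSV or JSON-lines files with configurable column names.
Character offsets everywhere in the package are 0-based, half-open,
Unicode code-point offsets into the report text.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

REPORT_TYPES = ("pathology", "imaging")

#: default input column names; callers may remap via ``column_map``
DEFAULT_COLUMNS = {
    "report_id": "report_id",
    "report_type": "report_type",
    "text": "text",
    "date": "date",
}


@dataclass(frozen=True)
class TextSpan:
    """Half-open character span ``[start, end)`` with its covered text."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValidationError(f"invalid span ({self.start}, {self.end})")

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "text": self.text}


@dataclass(frozen=True)
class ClinicalReport:
    """One free-text report: the unit of analysis for every algorithm."""

    report_id: str
    report_type: str
    text: str
    date: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if self.report_type not in REPORT_TYPES:
            raise ValidationError(
                f"report {self.report_id!r}: report_type must be one of "
                f"{REPORT_TYPES}, got {self.report_type!r}"
            )


def _resolve_columns(column_map: Optional[Mapping[str, str]]) -> dict:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(column_map)
    return cols


def _make_report(row: Mapping[str, object], cols: Mapping[str, str]) -> ClinicalReport:
    text = row.get(cols["text"])
    if text is None or (isinstance(text, float) and pd.isna(text)):
        logger.warning("report %r has null text; normalized to empty string",
                       row.get(cols["report_id"]))
        text = ""
    date = row.get(cols["date"])
    if date is not None and (date == "" or (isinstance(date, float) and pd.isna(date))):
        date = None
    return ClinicalReport(
        report_id=str(row[cols["report_id"]]),
        report_type=str(row[cols["report_type"]]),
        text=str(text),
        date=None if date is None else str(date),
    )


def read_corpus(
    path: str | Path,
    format: str = "csv",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ClinicalReport]:
    """Read a corpus of reports from ``path``, preserving file order.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"csv"`` or ``"jsonl"``.
    column_map:
        Optional remapping of the logical column names
        (``report_id``, ``report_type``, ``text``, ``date``) to file columns.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    cols = _resolve_columns(column_map)

    rows: list[Mapping[str, object]]
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        required = [cols["report_id"], cols["report_type"], cols["text"]]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigurationError(
                f"missing column(s) {missing} in {path} (have {list(df.columns)})"
            )
        if cols["date"] not in df.columns:
            df[cols["date"]] = None
        rows = df.to_dict(orient="records")
    elif format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValidationError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                for key in ("report_id", "report_type", "text"):
                    if cols[key] not in obj:
                        raise ConfigurationError(
                            f"{path}:{lineno}: missing field {cols[key]!r}"
                        )
                rows.append(obj)
    else:
        raise ConfigurationError(f"unknown corpus format: {format!r}")

    reports = [_make_report(row, cols) for row in rows]
    seen: dict[str, int] = {}
    duplicates = []
    for rep in reports:
        seen[rep.report_id] = seen.get(rep.report_id, 0) + 1
        if seen[rep.report_id] == 2:
            duplicates.append(rep.report_id)
    if duplicates:
        raise ValidationError(f"duplicate report_id values: {duplicates}")
    return reports


def write_corpus(
    reports: Iterable[ClinicalReport],
    path: str | Path,
    format: str = "csv",
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write reports back out in a ``read_corpus``-compatible layout."""
    cols = _resolve_columns(column_map)
    records = [
        {
            cols["report_id"]: r.report_id,
            cols["report_type"]: r.report_type,
            cols["text"]: r.text,
            cols["date"]: r.date,
        }
        for r in reports
    ]
    write_results(records, path, format=format)


def write_results(records: Sequence[Mapping[str, object]], path: str | Path,
                  format: str = "csv",
                  fieldnames: Optional[Sequence[str]] = None) -> None:
    """Write result rows (dicts sharing a schema) to CSV or JSONL.

    In CSV, nested lists/dicts are serialized as JSON strings so that cells
    survive quoting round-trips. ``fieldnames`` fixes the column order and
    allows an empty record list to still emit a header row.
    """
    path = Path(path)
    records = list(records)
    if format == "csv":
        flat = []
        for rec in records:
            row = {}
            for key, val in rec.items():
                if isinstance(val, (list, tuple, dict)):
                    val = json.dumps(val, ensure_ascii=False)
                row[key] = val
            flat.append(row)
        if fieldnames is not None:
            df = pd.DataFrame(flat, columns=list(fieldnames))
        else:
            df = pd.DataFrame(flat)
        df.to_csv(path, index=False, encoding="utf-8")
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(dict(rec), ensure_ascii=False))
                fh.write("\n")
    else:
        raise ConfigurationError(f"unknown results format: {format!r}")


def read_results(path: str | Path, format: str = "csv") -> list[dict]:
    """Read rows previously written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        return df.to_dict(orient="records")
    if format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        return rows
    raise ConfigurationError(f"unknown results format: {format!r}")
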