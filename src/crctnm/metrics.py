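"""Scoring of predictions against gold: confusion counts, micro-averaged
PPV/sensitivity, NPV/specificity against the no-value class, and 95%
Wilson score intervals.

A report contributes at most one value per category (the per-report
maximum), so micro-averaging pools true/false positives and false
negatives across value classes before forming each ratio. "No value" is
its own class and feeds NPV (no value predicted) and specificity (no
value present).
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from scipy.stats import norm

from . import tnm
from .corpus import read_results
from .errors import ValidationError


@dataclass
class ConfusionCounts:
    """Value-class and none-class confusion tallies for one category."""

    category: str
    tp: Counter = field(default_factory=Counter)
    fp: Counter = field(default_factory=Counter)
    fn: Counter = field(default_factory=Counter)
    tn_none: int = 0   # no value predicted, none present
    fn_none: int = 0   # no value predicted, but one was present
    fp_none: int = 0   # value predicted where none was present
    n_reports: int = 0
    n_value: int = 0   # reports whose gold carries a value


@dataclass
class MetricsRow:
    """Point estimates with Wilson bounds; None marks undefined ratios."""

    category: str
    num_report: int
    num_value: int
    ppv: Optional[float] = None
    ppv_lo: Optional[float] = None
    ppv_hi: Optional[float] = None
    npv: Optional[float] = None
    npv_lo: Optional[float] = None
    npv_hi: Optional[float] = None
    sensitivity: Optional[float] = None
    sensitivity_lo: Optional[float] = None
    sensitivity_hi: Optional[float] = None
    specificity: Optional[float] = None
    specificity_lo: Optional[float] = None
    specificity_hi: Optional[float] = None

    def to_row(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            out[key] = "" if val is None else val
        return out


METRIC_COLUMNS = tuple(MetricsRow("", 0, 0).__dict__.keys())


def wilson_interval(successes: int, trials: int, confidence: float = 0.95
                    ) -> Optional[tuple[float, float]]:
    """Two-sided Wilson score interval for a binomial proportion.

    Returns None when ``trials`` is zero (the ratio itself is undefined).
    Uses the exact normal quantile, not a rounded 1.96.
    """
    if not 0 <= successes <= trials:
        raise ValidationError(
            f"need 0 <= successes <= trials, got {successes}/{trials}")
    if trials == 0:
        return None
    z = float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    n = trials
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # at the boundaries the score equation has an exact root at 0 or 1
    lower = 0.0 if successes == 0 else max(0.0, centre - half)
    upper = 1.0 if successes == trials else min(1.0, centre + half)
    return (lower, upper)


def confusion(category: str,
              predictions: Mapping[str, Optional[str]],
              gold: Mapping[str, Optional[str]]) -> ConfusionCounts:
    """Tally per-value and none-class confusion counts over a corpus.

    Both mappings go from report_id to the per-report maximum value (None
    when no value was detected/present). Every prediction id must exist in
    gold; gold ids missing from predictions count as "no value predicted".
    """
    extra = set(predictions) - set(gold)
    if extra:
        raise ValidationError(
            f"predictions for unknown report_id(s): {sorted(extra)[:5]}")
    counts = ConfusionCounts(category=category)
    for rid, gold_val in gold.items():
        pred_val = predictions.get(rid)
        counts.n_reports += 1
        if gold_val is not None:
            counts.n_value += 1
        if pred_val is None and gold_val is None:
            counts.tn_none += 1
        elif pred_val is None:
            counts.fn_none += 1
            counts.fn[gold_val] += 1
        elif gold_val is None:
            counts.fp_none += 1
            counts.fp[pred_val] += 1
        elif pred_val == gold_val:
            counts.tp[pred_val] += 1
        else:
            counts.fp[pred_val] += 1
            counts.fn[gold_val] += 1
    return counts


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def micro_metrics(counts: ConfusionCounts, confidence: float = 0.95
                  ) -> MetricsRow:
    """Micro-averaged PPV/sensitivity and none-class NPV/specificity."""
    tp = sum(counts.tp.values())
    fp = sum(counts.fp.values())
    fn = sum(counts.fn.values())
    row = MetricsRow(category=counts.category, num_report=counts.n_reports,
                     num_value=counts.n_value)

    def fill(prefix: str, num: int, den: int) -> None:
        val = _ratio(num, den)
        setattr(row, prefix, val)
        if val is not None:
            lo, hi = wilson_interval(num, den, confidence)
            setattr(row, f"{prefix}_lo", lo)
            setattr(row, f"{prefix}_hi", hi)

    fill("ppv", tp, tp + fp)
    fill("sensitivity", tp, tp + fn)
    fill("npv", counts.tn_none, counts.tn_none + counts.fn_none)
    fill("specificity", counts.tn_none, counts.tn_none + counts.fp_none)
    return row


# ---------------------------------------------------------------------------
# file-level evaluation

_PRED_COLUMN = {"Tpre": "t_prefix", "T": "t", "N": "n", "M": "m", "V": "v",
                "R": "r", "L": "l", "Pn": "pn", "G": "g", "SM": "sm", "H": "h"}

SCENARIOS = ("explicit_only", "strict")


def _rank_max(category: str, values: Sequence[str]) -> Optional[str]:
    vals = [v for v in values if v]
    if not vals:
        return None
    if category == "Tpre":
        return vals[-1]
    informative = [v for v in vals if v != "X"]
    if not informative:
        return "X"
    return max(informative, key=lambda v: tnm.RANKING[category].index(v))


def _load_gold(gold_path: str | Path) -> list[dict]:
    records = read_results(gold_path, format="jsonl")
    if not all("report_id" in r for r in records):
        raise ValidationError(f"gold records need a report_id field: {gold_path}")
    return records


def evaluate_tnm(pred_rows: Sequence[Mapping], gold_records: Sequence[Mapping],
                 scenario: str = "strict") -> list[MetricsRow]:
    """Score TNM prediction rows against gold records, per category.

    ``strict`` treats implicit gold stages as stages to be found (misses
    are errors) and historical-only retrievals as false positives.
    ``explicit_only`` excludes implicit (report, category) pairs from the
    tally and accepts historical stages as correct retrievals.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    gold_by_id = {r["report_id"]: r for r in gold_records}
    if len(gold_by_id) != len(gold_records):
        raise ValidationError("duplicate report_id in gold records")

    rows = []
    for cat in tnm.CATEGORIES:
        col = _PRED_COLUMN[cat]
        predictions: dict[str, Optional[str]] = {}
        for row in pred_rows:
            rid = str(row["report_id"])
            val = row.get(col) or None
            predictions[rid] = str(val) if val is not None else None

        gold_map: dict[str, Optional[str]] = {}
        for rid, rec in gold_by_id.items():
            explicit = (rec.get("tnm_gold") or {}).get(cat)
            historical = (rec.get("tnm_historical") or {}).get(cat)
            implicit = (rec.get("tnm_implicit") or {}).get(cat)
            if scenario == "strict":
                gold_map[rid] = _rank_max(
                    cat, [v for v in (explicit, implicit) if v])
            else:
                if implicit:
                    continue  # not an explicit-extraction error either way
                gold_map[rid] = _rank_max(
                    cat, [v for v in (explicit, historical) if v])
        preds = {rid: v for rid, v in predictions.items() if rid in gold_map}
        unknown = set(predictions) - set(gold_by_id)
        if unknown:
            raise ValidationError(
                f"predictions for unknown report_id(s): {sorted(unknown)[:5]}")
        rows.append(micro_metrics(confusion(cat, preds, gold_map)))
    return rows


def evaluate_crc(pred_rows: Sequence[Mapping], gold_records: Sequence[Mapping]
                 ) -> list[MetricsRow]:
    """Score CRC status predictions: a single binary category."""
    gold_map: dict[str, Optional[str]] = {}
    for rec in gold_records:
        gold_map[str(rec["report_id"])] = (
            "positive" if rec.get("crc_status") else None)
    predictions: dict[str, Optional[str]] = {}
    for row in pred_rows:
        raw = row.get("crc_status")
        flag = raw if isinstance(raw, bool) else str(raw).lower() == "true"
        predictions[str(row["report_id"])] = "positive" if flag else None
    return [micro_metrics(confusion("CRC", predictions, gold_map))]


def evaluate(pred_path: str | Path, gold_path: str | Path,
             task: str = "tnm", scenario: str = "strict",
             pred_format: str = "csv") -> list[MetricsRow]:
    """Evaluate a prediction file against a gold JSONL file."""
    pred_rows = read_results(pred_path, format=pred_format)
    gold_records = _load_gold(gold_path)
    if task == "tnm":
        return evaluate_tnm(pred_rows, gold_records, scenario=scenario)
    if task == "crc":
        return evaluate_crc(pred_rows, gold_records)
    raise ValidationError(f"unknown task {task!r}")


def format_percent(value: Optional[float]) -> str:
    """Render a proportion as a one-decimal percentage, half-up; '-' if absent."""
    if value is None:
        return "-"
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(value * 100).quantize(Decimal("0.1"),
                                             rounding=ROUND_HALF_UP))
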