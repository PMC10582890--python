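"""Ingest catalogue-style performance-metric tables and summarize DR_5.

The pipeline is parse -> plausibility filter -> DR_5 summary:

* :func:`parse_performance_table` reads a long-format TSV/CSV (one
  metric estimate per row) with a configurable column map and a
  spelling table for metric kinds; malformed rows are collected into a
  rejects report rather than silently dropped.
* :func:`filter_records` drops continuous-trait records and implausible
  values (OR/HR per SD < 1, AUC < 0.5, C-index outside (0.5, 1)),
  returning an exact accounting of what was removed.
* :func:`summarize_dr5` converts each retained estimate to a detection
  rate at a 5% false positive rate and reports medians and quartiles
  overall, per trait, or per metric kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MetricKind,
    ReportedMetric,
    RiskModel,
    ScreeningCut,
    ValidationError,
    delta_from_metric,
    detection_rate,
)

__all__ = [
    "CatalogConfigError",
    "CatalogSummary",
    "FilterReport",
    "ParseResult",
    "PerformanceRecord",
    "RejectedRow",
    "TableDialect",
    "DEFAULT_DIALECT",
    "dr5_for_record",
    "filter_records",
    "parse_performance_table",
    "summarize_dr5",
]


class CatalogConfigError(ValidationError):
    """The table does not match the configured column map."""


#: canonical logical column names -> default file headers
DEFAULT_COLUMNS: Mapping[str, str] = {
    "score_id": "score_id",
    "trait_id": "trait_id",
    "trait_type": "trait_type",
    "metric_kind": "metric_kind",
    "metric_value": "metric_value",
    "publication_id": "publication_id",
}

#: observed spellings of metric kinds (case-insensitive, stripped)
METRIC_ALIASES: Mapping[str, MetricKind] = {
    "or_per_sd": MetricKind.OR_PER_SD,
    "or": MetricKind.OR_PER_SD,
    "odds ratio": MetricKind.OR_PER_SD,
    "odds ratio (or, per sd)": MetricKind.OR_PER_SD,
    "odds ratio (or)": MetricKind.OR_PER_SD,
    "hr_per_sd": MetricKind.HR_PER_SD,
    "hr": MetricKind.HR_PER_SD,
    "hazard ratio": MetricKind.HR_PER_SD,
    "hazard ratio (hr, per sd)": MetricKind.HR_PER_SD,
    "hazard ratio (hr)": MetricKind.HR_PER_SD,
    "auc": MetricKind.AUC,
    "auroc": MetricKind.AUC,
    "area under the receiver operating characteristic curve": MetricKind.AUC,
    "area under the receiver-operating characteristic curve (auroc)": MetricKind.AUC,
    "c_index": MetricKind.C_INDEX,
    "c-index": MetricKind.C_INDEX,
    "c index": MetricKind.C_INDEX,
    "concordance statistic (c-index)": MetricKind.C_INDEX,
}

_TRAIT_TYPES = {"binary", "continuous"}


@dataclass(frozen=True)
class TableDialect:
    """How to read one flavour of performance-metrics table."""

    sep: str = "\t"
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    metric_aliases: Mapping[str, MetricKind] = field(
        default_factory=lambda: dict(METRIC_ALIASES)
    )

    def resolve_kind(self, raw: str) -> MetricKind | None:
        return self.metric_aliases.get(raw.strip().lower())


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class PerformanceRecord:
    """One published metric estimate for one score."""

    score_id: str
    trait_id: str
    trait_type: Literal["binary", "continuous"]
    metric: ReportedMetric
    publication_id: str


@dataclass(frozen=True)
class RejectedRow:
    line: int  # 1-based data-row index in the source file
    reason: str
    raw: Mapping[str, str]


@dataclass(frozen=True)
class ParseResult:
    records: tuple[PerformanceRecord, ...]
    rejects: tuple[RejectedRow, ...]


def parse_performance_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> ParseResult:
    """Read a performance-metrics table into validated records.

    Out-of-range metric *values* are kept (the plausibility filter owns
    those); rows with missing fields, unknown metric kinds, non-numeric
    values, or unknown trait types go to the rejects report.
    """
    frame = pd.read_csv(
        path, sep=dialect.sep, dtype=str, keep_default_na=False, engine="python"
    )
    missing = [h for h in dialect.columns.values() if h not in frame.columns]
    if missing:
        raise CatalogConfigError(
            f"missing mandatory column(s) {missing}; found {list(frame.columns)}"
        )

    col = dialect.columns
    records: list[PerformanceRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))

        def reject(reason: str) -> None:
            rejects.append(RejectedRow(line=i, reason=reason, raw=raw))

        score_id = raw[col["score_id"]].strip()
        if not score_id:
            reject("empty score_id")
            continue
        trait_type = raw[col["trait_type"]].strip().lower()
        if trait_type not in _TRAIT_TYPES:
            reject(f"unknown trait_type {raw[col['trait_type']]!r}")
            continue
        kind = dialect.resolve_kind(raw[col["metric_kind"]])
        if kind is None:
            reject(f"unknown metric kind {raw[col['metric_kind']]!r}")
            continue
        value_text = raw[col["metric_value"]].strip()
        try:
            value = float(value_text)
        except ValueError:
            reject(f"non-numeric metric value {value_text!r}")
            continue
        records.append(
            PerformanceRecord(
                score_id=score_id,
                trait_id=raw[col["trait_id"]].strip(),
                trait_type=trait_type,  # type: ignore[arg-type]
                metric=ReportedMetric(kind, value, validate=False),
                publication_id=raw[col["publication_id"]].strip(),
            )
        )
    return ParseResult(records=tuple(records), rejects=tuple(rejects))


@dataclass(frozen=True)
class FilterReport:
    """Exact accounting of the plausibility filter."""

    n_input: int
    n_removed_continuous: int
    n_removed_or_hr_lt_1: int
    n_removed_auc_lt_half: int
    n_removed_cindex_implausible: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_continuous
            + self.n_removed_or_hr_lt_1
            + self.n_removed_auc_lt_half
            + self.n_removed_cindex_implausible
        )
        if self.n_input != self.n_retained + removed:
            raise ValidationError("filter report counts do not reconcile")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_continuous": self.n_removed_continuous,
            "n_removed_or_hr_lt_1": self.n_removed_or_hr_lt_1,
            "n_removed_auc_lt_half": self.n_removed_auc_lt_half,
            "n_removed_cindex_implausible": self.n_removed_cindex_implausible,
            "n_retained": self.n_retained,
        }


def filter_records(
    records: Sequence[PerformanceRecord],
) -> tuple[list[PerformanceRecord], FilterReport]:
    """Apply the plausibility rules; every retained record converts to delta >= 0."""
    retained: list[PerformanceRecord] = []
    n_cont = n_ratio = n_auc = n_cindex = 0
    for rec in records:
        kind, value = rec.metric.kind, rec.metric.value
        if rec.trait_type == "continuous":
            n_cont += 1
        elif kind in (MetricKind.OR_PER_SD, MetricKind.HR_PER_SD) and value < 1.0:
            n_ratio += 1
        elif kind is MetricKind.AUC and value < 0.5:
            n_auc += 1
        elif kind is MetricKind.C_INDEX and not 0.5 < value < 1.0:
            n_cindex += 1
        else:
            retained.append(rec)
    report = FilterReport(
        n_input=len(records),
        n_removed_continuous=n_cont,
        n_removed_or_hr_lt_1=n_ratio,
        n_removed_auc_lt_half=n_auc,
        n_removed_cindex_implausible=n_cindex,
        n_retained=len(retained),
    )
    return retained, report


def dr5_for_record(record: PerformanceRecord, fpr: float = 0.05) -> float:
    """Detection rate at the given FPR implied by one record's metric."""
    model: RiskModel = delta_from_metric(
        ReportedMetric(record.metric.kind, record.metric.value)
    )
    return detection_rate(model, ScreeningCut.from_fpr(fpr))


@dataclass(frozen=True)
class CatalogSummary:
    """Median and quartiles of record-level DR_5 for one group."""

    group_by: str  # "overall" | "trait_id" | "metric_kind"
    group: str
    n_records: int
    n_scores: int
    median_dr5: float
    iqr_lo: float
    iqr_hi: float

    def as_dict(self) -> dict[str, object]:
        return {
            "group_by": self.group_by,
            "group": self.group,
            "n_records": self.n_records,
            "n_scores": self.n_scores,
            "median_dr5": self.median_dr5,
            "iqr_lo": self.iqr_lo,
            "iqr_hi": self.iqr_hi,
        }


def _summary(
    group_by: str, group: str, records: Sequence[PerformanceRecord], fpr: float,
    per_score: bool,
) -> CatalogSummary:
    if per_score:
        by_score: dict[str, list[float]] = {}
        for rec in records:
            by_score.setdefault(rec.score_id, []).append(dr5_for_record(rec, fpr))
        values = np.array([np.median(v) for v in by_score.values()])
    else:
        values = np.array([dr5_for_record(r, fpr) for r in records])
    lo, med, hi = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return CatalogSummary(
        group_by=group_by,
        group=group,
        n_records=len(records),
        n_scores=len({r.score_id for r in records}),
        median_dr5=float(med),
        iqr_lo=float(lo),
        iqr_hi=float(hi),
    )


def summarize_dr5(
    records: Sequence[PerformanceRecord],
    group_by: Literal["overall", "trait_id", "metric_kind"] = "overall",
    fpr: float = 0.05,
    per_score: bool = False,
) -> list[CatalogSummary]:
    """Quantile summaries of DR_5 values.

    The aggregation unit is the metric estimate (record); pass
    ``per_score=True`` to collapse each score to the median of its
    estimates first.  Quantiles use linear interpolation between order
    statistics.
    """
    if not records:
        warnings.warn("no records to summarize; returning empty list", stacklevel=2)
        return []
    if group_by == "overall":
        return [_summary("overall", "overall", records, fpr, per_score)]
    if group_by == "trait_id":
        key = lambda r: r.trait_id  # noqa: E731
    elif group_by == "metric_kind":
        key = lambda r: r.metric.kind.value  # noqa: E731
    else:
        raise ValidationError(f"unknown group_by {group_by!r}")
    groups: dict[str, list[PerformanceRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    return [
        _summary(group_by, name, grp, fpr, per_score)
        for name, grp in sorted(groups.items())
    ]


def summaries_to_frame(summaries: Iterable[CatalogSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
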