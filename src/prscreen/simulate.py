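"""Synthetic inputs: score cohorts and mock catalogue tables.

Individual-level cohorts are drawn from the generative model the rest of
the package assumes -- unaffected scores standard normal, affected
scores normal with mean ``delta`` and unit SD, affected status Bernoulli
-- so empirical estimates can be checked against the closed forms.
Mock catalogue tables come with a ground-truth manifest recording every
planted implausible value, for exact pipeline checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .catalog import DEFAULT_DIALECT, TableDialect
from .core import MetricKind, ReportedMetric, RiskModel, ValidationError, metric_from_delta

__all__ = [
    "Cohort",
    "CohortSpec",
    "DegenerateCohortError",
    "EmpiricalMetrics",
    "MockCatalogSpec",
    "estimate_metrics_empirical",
    "make_mock_catalog",
    "simulate_prs_cohort",
]


class DegenerateCohortError(ValidationError):
    """Too few affected or unaffected individuals to estimate metrics."""


@dataclass(frozen=True)
class CohortSpec:
    n: int
    delta: float
    risk: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        if not 0.0 < self.risk < 1.0:
            raise ValidationError(f"risk must be in (0, 1), got {self.risk}")
        RiskModel(abs(self.delta))  # finiteness check


@dataclass(frozen=True)
class Cohort:
    """Individual-level scores with affected flags."""

    score: np.ndarray
    affected: np.ndarray
    spec: CohortSpec

    @property
    def n_affected(self) -> int:
        return int(self.affected.sum())

    @property
    def n_unaffected(self) -> int:
        return int((~self.affected).sum())


def simulate_prs_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the two-Gaussian model; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    affected = rng.random(spec.n) < spec.risk
    score = rng.standard_normal(spec.n) + spec.delta * affected
    return Cohort(score=score, affected=affected, spec=spec)


@dataclass(frozen=True)
class EmpiricalMetrics:
    auc: float
    or_per_sd: float
    dr: float
    fpr: float


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordance probability via the rank-sum statistic."""
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def estimate_metrics_empirical(cohort: Cohort, fpr: float = 0.05) -> EmpiricalMetrics:
    """Estimate (AUC, OR per SD, DR at ``fpr``) from individual-level data.

    AUC by the rank/concordance statistic; OR per SD by maximum
    likelihood logistic regression on the score scaled to sample-SD
    units; DR as the affected fraction above the empirical unaffected
    ``1 - fpr`` quantile.
    """
    pos = cohort.score[cohort.affected]
    neg = cohort.score[~cohort.affected]
    if len(pos) < 50 or len(neg) < 50:
        raise DegenerateCohortError(
            f"need >= 50 affected and unaffected, got {len(pos)}/{len(neg)}"
        )

    auc = _rank_auc(pos, neg)

    x_sd = cohort.score / cohort.score.std(ddof=1)
    design = sm.add_constant(x_sd)
    fit = sm.Logit(cohort.affected.astype(float), design).fit(disp=False)
    or_per_sd = float(np.exp(fit.params[1]))

    threshold = float(np.quantile(neg, 1.0 - fpr))
    dr = float((pos > threshold).mean())
    return EmpiricalMetrics(auc=auc, or_per_sd=or_per_sd, dr=dr, fpr=fpr)


# -- mock catalogue -----------------------------------------------------------

_KIND_SPELLINGS = {
    MetricKind.OR_PER_SD: "Odds Ratio (OR, per SD)",
    MetricKind.HR_PER_SD: "Hazard Ratio (HR, per SD)",
    MetricKind.AUC: "AUROC",
    MetricKind.C_INDEX: "C-index",
}


@dataclass(frozen=True)
class MockCatalogSpec:
    """Plan for a catalogue table with known ground truth.

    Valid binary records get a true mean difference drawn from
    ``|Normal(delta_mean, delta_sd)|`` and a metric value computed from
    it; planted violations and continuous-trait rows are counted exactly
    in the manifest.
    """

    n_records: int
    metric_mix: Sequence[MetricKind] = (
        MetricKind.OR_PER_SD,
        MetricKind.HR_PER_SD,
        MetricKind.AUC,
        MetricKind.C_INDEX,
    )
    delta_mean: float = 0.5
    delta_sd: float = 0.2
    n_or_hr_lt_1: int = 0
    n_auc_lt_half: int = 0
    n_cindex_implausible: int = 0
    n_continuous: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_or_hr_lt_1
            + self.n_auc_lt_half
            + self.n_cindex_implausible
            + self.n_continuous
        )
        if planted > self.n_records:
            raise ValidationError(
                f"planted rows ({planted}) exceed n_records ({self.n_records})"
            )
        if not self.metric_mix:
            raise ValidationError("metric_mix must be non-empty")


def make_mock_catalog(
    spec: MockCatalogSpec,
    path: str | Path,
    manifest_path: str | Path | None = None,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> dict:
    """Write a parseable mock table; return the ground-truth manifest.

    The manifest records the planted violation counts and, for each
    valid row, the true delta — enough to predict the filter report and
    the summary medians exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_valid = spec.n_records - (
        spec.n_or_hr_lt_1
        + spec.n_auc_lt_half
        + spec.n_cindex_implausible
        + spec.n_continuous
    )

    rows: list[dict[str, str]] = []
    truths: list[dict[str, object]] = []

    def add_row(kind: MetricKind, value: float, trait_type: str, true_delta=None):
        i = len(rows)
        rows.append(
            {
                "score_id": f"MPS{i:06d}",
                "trait_id": f"EFO_{9000000 + i}",
                "trait_type": trait_type,
                "metric_kind": _KIND_SPELLINGS[kind],
                "metric_value": repr(float(value)),
                "publication_id": f"MPP{i % 7:06d}",
            }
        )
        truths.append(
            {
                "score_id": f"MPS{i:06d}",
                "kind": kind.value,
                "value": float(value),
                "trait_type": trait_type,
                "true_delta": true_delta,
            }
        )

    deltas = np.abs(rng.normal(spec.delta_mean, spec.delta_sd, size=n_valid))
    for j, d in enumerate(deltas):
        kind = spec.metric_mix[j % len(spec.metric_mix)]
        value = metric_from_delta(RiskModel(float(d)), kind)
        # keep rank metrics clear of the filter boundary
        if kind in (MetricKind.AUC, MetricKind.C_INDEX):
            value = min(max(value, 0.500001), 0.999999)
        add_row(kind, value, "binary", true_delta=float(d))

    for _ in range(spec.n_or_hr_lt_1):
        kind = MetricKind.OR_PER_SD if rng.random() < 0.5 else MetricKind.HR_PER_SD
        add_row(kind, rng.uniform(0.3, 0.99), "binary")
    for _ in range(spec.n_auc_lt_half):
        add_row(MetricKind.AUC, rng.uniform(0.2, 0.49), "binary")
    for _ in range(spec.n_cindex_implausible):
        add_row(MetricKind.C_INDEX, float(rng.choice([632.0, 1.5, 12.0])), "binary")
    for _ in range(spec.n_continuous):
        add_row(MetricKind.AUC, rng.uniform(0.55, 0.9), "continuous")

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    truths = [truths[i] for i in order]

    header = [dialect.columns[k] for k in (
        "score_id", "trait_id", "trait_type", "metric_kind", "metric_value",
        "publication_id",
    )]
    logical = ["score_id", "trait_id", "trait_type", "metric_kind", "metric_value",
               "publication_id"]
    lines = [dialect.sep.join(header)]
    lines += [dialect.sep.join(row[k] for k in logical) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")

    manifest = {
        "n_records": spec.n_records,
        "n_valid": n_valid,
        "planted": {
            "n_continuous": spec.n_continuous,
            "n_or_hr_lt_1": spec.n_or_hr_lt_1,
            "n_auc_lt_half": spec.n_auc_lt_half,
            "n_cindex_implausible": spec.n_cindex_implausible,
        },
        "records": truths,
        "seed": spec.seed,
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return manifest
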