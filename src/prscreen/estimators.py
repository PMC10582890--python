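"""Likelihood-ratio constructions and the calculators built on them.

Three likelihood ratios, all functions of the mean difference ``delta``:

* threshold (screening): ``DR / FPR`` above a cut-off;
* centile (individual prediction): the ratio of the affected and
  unaffected density heights at a score value, ``exp(delta*z - delta^2/2)``;
* quantile group (stratification): the ratio of the areas the two
  densities place on a slice of the unaffected distribution.

Centiles and quantiles always refer to the *unaffected* distribution.
Multiplying any of these by the background odds of becoming affected
gives the posterior odds for the individual or group of interest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    Odds,
    RiskModel,
    ScreeningCut,
    ValidationError,
    detection_rate,
)

__all__ = [
    "CentileQuery",
    "QuantileGroup",
    "StratificationTable",
    "StratumRow",
    "TailAnalysis",
    "allocate_counts",
    "individual_odds",
    "lr_at_centile",
    "lr_positive",
    "lr_quantile_group",
    "odds_given_positive",
    "stratification_table",
    "tail_analysis",
    "top_vs_bottom_odds_ratio",
]

TABLE_COLUMNS = [
    "group_lo",
    "group_hi",
    "lr",
    "odds_1_in_n",
    "n_affected",
    "n_unaffected",
    "share_of_cases",
]


@dataclass(frozen=True)
class CentileQuery:
    """A score position stated as a centile of the unaffected distribution.

    Construct via :meth:`from_percent` (e.g. 97.5) or :meth:`from_fraction`
    (e.g. 0.975); the unit is always explicit, never guessed from
    magnitude.  ``centile`` is stored in percent.
    """

    centile: float
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.centile < 100.0:
            raise ValidationError(f"centile must be in (0, 100), got {self.centile}")
        implied = float(norm.ppf(self.centile / 100.0))
        if self.z is None:
            object.__setattr__(self, "z", implied)
        elif abs(float(self.z) - implied) > 1e-9:
            raise ValidationError(
                f"z {self.z} inconsistent with centile {self.centile} "
                f"(expected {implied})"
            )

    @classmethod
    def from_percent(cls, percent: float) -> "CentileQuery":
        return cls(centile=float(percent))

    @classmethod
    def from_fraction(cls, fraction: float) -> "CentileQuery":
        return cls(centile=float(fraction) * 100.0)


@dataclass(frozen=True)
class QuantileGroup:
    """A slice [q_lo, q_hi] of the unaffected distribution's probability mass."""

    q_lo: float
    q_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_lo < self.q_hi <= 1.0:
            raise ValidationError(
                f"need 0 <= q_lo < q_hi <= 1, got [{self.q_lo}, {self.q_hi}]"
            )

    @property
    def width(self) -> float:
        return self.q_hi - self.q_lo


def lr_positive(model: RiskModel, cut: ScreeningCut) -> float:
    """Threshold likelihood ratio: detection rate over false positive rate."""
    return detection_rate(model, cut) / cut.fpr


def lr_at_centile(model: RiskModel, q: CentileQuery) -> float:
    """Density-height ratio at a centile: exp(delta*z - delta^2 / 2)."""
    d = model.delta
    return math.exp(d * q.z - 0.5 * d * d)


def lr_quantile_group(model: RiskModel, g: QuantileGroup) -> float:
    """Area ratio on a quantile slice of the unaffected distribution."""
    z_lo = float(norm.ppf(g.q_lo))  # -inf at q_lo = 0
    z_hi = float(norm.ppf(g.q_hi))  # +inf at q_hi = 1
    affected_mass = float(norm.cdf(z_hi - model.delta) - norm.cdf(z_lo - model.delta))
    return affected_mass / g.width


def individual_odds(model: RiskModel, q: CentileQuery, background: Odds) -> Odds:
    """Posterior odds for an individual scoring at a given centile."""
    return background.times(lr_at_centile(model, q))


def odds_given_positive(model: RiskModel, cut: ScreeningCut, background: Odds) -> Odds:
    """Posterior odds of becoming affected given a positive screen."""
    return background.times(lr_positive(model, cut))


class TailAnalysis(NamedTuple):
    lr: float
    odds: Odds
    share_of_cases: float


def tail_analysis(
    model: RiskModel, top_fraction: float, background: Odds
) -> TailAnalysis:
    """Likelihood ratio, posterior odds, and case share for the upper tail.

    ``share_of_cases`` is the fraction of all affected individuals whose
    score exceeds the unaffected ``1 - top_fraction`` quantile.
    """
    if not 0.0 < top_fraction <= 0.5:
        raise ValidationError(f"top_fraction must be in (0, 0.5], got {top_fraction}")
    group = QuantileGroup(1.0 - top_fraction, 1.0)
    lr = lr_quantile_group(model, group)
    share = lr * top_fraction  # = 1 - Phi(z_cut - delta)
    return TailAnalysis(lr=lr, odds=background.times(lr), share_of_cases=share)


def top_vs_bottom_odds_ratio(model: RiskModel, fraction: float) -> float:
    """Odds ratio comparing the symmetric top and bottom tails.

    The ratio of the two tail-area likelihood ratios; independent of the
    background odds.
    """
    if not 0.0 < fraction < 0.5:
        raise ValidationError(f"fraction must be in (0, 0.5), got {fraction}")
    top = lr_quantile_group(model, QuantileGroup(1.0 - fraction, 1.0))
    bottom = lr_quantile_group(model, QuantileGroup(0.0, fraction))
    return top / bottom


# -- stratification -----------------------------------------------------------


@dataclass(frozen=True)
class StratumRow:
    group: QuantileGroup
    lr: float
    odds: Odds
    n_affected: int
    n_unaffected: int
    share_of_cases: float  # continuous (area-based); canonical


@dataclass(frozen=True)
class StratificationTable:
    """Per-quantile-group likelihood ratios, odds and integer head counts."""

    rows: tuple[StratumRow, ...]
    population: int
    background: Odds

    @property
    def n_affected_total(self) -> int:
        return sum(r.n_affected for r in self.rows)

    @property
    def n_unaffected_total(self) -> int:
        return sum(r.n_unaffected for r in self.rows)

    def count_shares(self) -> list[float]:
        total = self.n_affected_total
        if total == 0:
            return [0.0] * len(self.rows)
        return [r.n_affected / total for r in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_lo": [r.group.q_lo for r in self.rows],
                "group_hi": [r.group.q_hi for r in self.rows],
                "lr": [r.lr for r in self.rows],
                "odds_1_in_n": [r.odds.one_in_n_denominator() for r in self.rows],
                "n_affected": [r.n_affected for r in self.rows],
                "n_unaffected": [r.n_unaffected for r in self.rows],
                "share_of_cases": [r.share_of_cases for r in self.rows],
            },
            columns=TABLE_COLUMNS,
        )

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        payload = {
            "population": self.population,
            "background": {
                "numerator": self.background.numerator,
                "denominator": self.background.denominator,
            },
            "rows": self.to_dataframe().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def allocate_counts(total: int, weights: Iterable[float]) -> list[int]:
    """Allocate ``total`` whole units proportionally to ``weights``.

    Largest-remainder method: floor each expected count, then hand the
    leftover units to the cells with the largest fractional parts, so
    the allocation sums to ``total`` exactly.
    """
    w = np.asarray(list(weights), dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with a positive sum")
    expected = total * w / w.sum()
    base = np.floor(expected).astype(int)
    shortfall = total - int(base.sum())
    if shortfall:
        order = np.argsort(-(expected - base), kind="stable")
        base[order[:shortfall]] += 1
    return base.tolist()


def stratification_table(
    model: RiskModel,
    n_groups: int,
    background: Odds,
    population: int,
) -> StratificationTable:
    """Equal-width stratification of a hypothetical cohort.

    The unaffected distribution is cut into ``n_groups`` equal-probability
    slices.  Affected counts are allocated by ``width * lr`` (the affected
    mass per slice), unaffected counts by width; both allocations
    reconcile to the rounded totals exactly.
    """
    if n_groups < 2:
        raise ValidationError(f"n_groups must be >= 2, got {n_groups}")
    if population <= 0:
        raise ValidationError(f"population must be > 0, got {population}")

    edges = np.linspace(0.0, 1.0, n_groups + 1)
    groups = [QuantileGroup(float(lo), float(hi)) for lo, hi in zip(edges, edges[1:])]
    lrs = [lr_quantile_group(model, g) for g in groups]

    n_affected_total = round(population * background.risk)
    n_unaffected_total = population - n_affected_total
    affected_weights = [g.width * lr for g, lr in zip(groups, lrs)]
    n_affected = allocate_counts(n_affected_total, affected_weights)
    n_unaffected = allocate_counts(n_unaffected_total, [g.width for g in groups])

    rows = tuple(
        StratumRow(
            group=g,
            lr=lr,
            odds=background.times(lr),
            n_affected=na,
            n_unaffected=nu,
            share_of_cases=w,  # width*lr integrates the affected density
        )
        for g, lr, na, nu, w in zip(groups, lrs, n_affected, n_unaffected, affected_weights)
    )
    return StratificationTable(rows=rows, population=population, background=background)
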