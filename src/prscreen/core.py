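"""Binormal equal-variance screening model.

The whole calculus runs off a single parameter: the standardized mean
difference ``delta`` between the score distributions of affected and
unaffected individuals, both assumed Gaussian with unit standard
deviation (the unaffected distribution is standard normal).  Published
discrimination metrics -- odds ratio per SD, hazard ratio per SD, AUC,
C-index -- each map to ``delta``, after which detection rates,
likelihood ratios and posterior odds follow in closed form.

Conventions
-----------
* ``delta = ln(OR_SD)`` and ``delta = ln(HR_SD)`` (hazard ratios pooled
  with odds ratios; a documented assumption).
* ``delta = sqrt(2) * Phi^-1(AUC)``; the C-index is treated as an AUC.
* A screening cut-off is stated as a false positive rate ``fpr``; the
  implied threshold on the unaffected scale is the upper-tail quantile
  ``z_cut = Phi^-1(1 - fpr)``.
* Detection rate ``DR = 1 - Phi(z_cut - delta)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import InitVar, dataclass
from enum import Enum

from scipy.stats import norm

__all__ = [
    "MetricKind",
    "Odds",
    "ReportedMetric",
    "RiskDirectionWarning",
    "RiskModel",
    "ScreeningCut",
    "ValidationError",
    "apply_lr",
    "delta_from_metric",
    "detection_rate",
    "format_one_in_n",
    "metric_from_delta",
    "odds_from_risk",
    "required_delta_for_dr",
    "required_metric_for_dr",
    "risk_from_odds",
    "round_half_away",
]


class ValidationError(ValueError):
    """An input violates a documented bound."""


class RiskDirectionWarning(UserWarning):
    """A metric implies a protective (negative-delta) score direction."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class MetricKind(str, Enum):
    """Published discrimination metrics convertible to ``delta``."""

    OR_PER_SD = "or_per_sd"
    HR_PER_SD = "hr_per_sd"
    AUC = "auc"
    C_INDEX = "c_index"


_RATIO_KINDS = frozenset({MetricKind.OR_PER_SD, MetricKind.HR_PER_SD})
_RANK_KINDS = frozenset({MetricKind.AUC, MetricKind.C_INDEX})


@dataclass(frozen=True)
class ReportedMetric:
    """One published performance estimate.

    Parameters
    ----------
    kind :
        Metric family; accepts a :class:`MetricKind` or its string value.
    value :
        The reported number.  Ratio metrics must be positive, rank
        metrics must lie in (0, 1).
    validate :
        Pass ``False`` to carry an out-of-range value (e.g. a mis-keyed
        catalogue entry destined for the plausibility filter).  Such a
        metric still refuses conversion via :func:`delta_from_metric`.
    """

    kind: MetricKind
    value: float
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "kind", MetricKind(self.kind))
        object.__setattr__(self, "value", float(self.value))
        if validate:
            self.check()

    def check(self) -> None:
        """Raise :class:`ValidationError` naming any violated bound."""
        if not math.isfinite(self.value):
            raise ValidationError(f"{self.kind.value} must be finite, got {self.value}")
        if self.kind in _RATIO_KINDS and self.value <= 0:
            raise ValidationError(f"{self.kind.value} must be > 0, got {self.value}")
        if self.kind in _RANK_KINDS and not 0.0 < self.value < 1.0:
            raise ValidationError(
                f"{self.kind.value} must be in (0, 1), got {self.value}"
            )


@dataclass(frozen=True)
class RiskModel:
    """The standardized mean difference between affected and unaffected scores.

    ``delta`` is in unaffected-SD units.  Negative values (protective
    orientation) are accepted and propagated, with a warning, so that
    mis-oriented records remain analyzable.
    """

    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", float(self.delta))
        if not math.isfinite(self.delta):
            raise ValidationError(f"delta must be finite, got {self.delta}")
        if self.delta < 0:
            warnings.warn(
                f"delta = {self.delta} implies a protective score direction; "
                "propagating as-is",
                RiskDirectionWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ScreeningCut:
    """A cut-off stated as a false positive rate on the unaffected distribution.

    ``z_cut`` is derived from ``fpr`` when omitted; when both are given
    they must agree to 1e-9.
    """

    fpr: float
    z_cut: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fpr < 1.0:
            raise ValidationError(f"fpr must be in (0, 1), got {self.fpr}")
        implied = float(norm.isf(self.fpr))
        if self.z_cut is None:
            object.__setattr__(self, "z_cut", implied)
        elif abs(float(self.z_cut) - implied) > 1e-9:
            raise ValidationError(
                f"z_cut {self.z_cut} inconsistent with fpr {self.fpr} "
                f"(expected {implied})"
            )

    @classmethod
    def from_fpr(cls, fpr: float) -> "ScreeningCut":
        return cls(fpr=fpr)


@dataclass(frozen=True)
class Odds:
    """Odds ``a:b`` of being affected versus unaffected.

    Stored unnormalized so that e.g. ``2.4:19`` survives intermediate
    arithmetic; display normalizes to ``1:N``.
    """

    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "numerator", float(self.numerator))
        object.__setattr__(self, "denominator", float(self.denominator))
        if self.numerator < 0:
            raise ValidationError(f"odds numerator must be >= 0, got {self.numerator}")
        if self.denominator <= 0:
            raise ValidationError(
                f"odds denominator must be > 0, got {self.denominator}"
            )

    @property
    def risk(self) -> float:
        """Probability a/(a+b)."""
        return self.numerator / (self.numerator + self.denominator)

    @property
    def ratio(self) -> float:
        """a/b."""
        return self.numerator / self.denominator

    @classmethod
    def from_risk(cls, risk: float) -> "Odds":
        if not 0.0 <= risk < 1.0:
            raise ValidationError(f"risk must be in [0, 1), got {risk}")
        return cls(risk, 1.0 - risk)

    @classmethod
    def parse(cls, text: str) -> "Odds":
        """Parse ``"a:b"``, a decimal probability, or ``"x%"``."""
        token = text.strip()
        try:
            if ":" in token:
                a, b = token.split(":")
                return cls(float(a), float(b))
            if token.endswith("%"):
                return cls.from_risk(float(token[:-1]) / 100.0)
            return cls.from_risk(float(token))
        except ValidationError:
            raise
        except ValueError as exc:
            raise ValidationError(f"cannot parse odds from {text!r}") from exc

    def times(self, lr: float) -> "Odds":
        """Scale the affected side by a likelihood ratio."""
        if lr <= 0:
            raise ValidationError(f"likelihood ratio must be > 0, got {lr}")
        return Odds(self.numerator * lr, self.denominator)

    def one_in_n_denominator(self) -> int:
        """N of the normalized ``1:N`` form, rounded half away from zero."""
        if self.numerator == 0:
            raise ValidationError("cannot normalize 0:b odds to 1:N form")
        return round_half_away(self.denominator / self.numerator)

    def one_in_n(self) -> str:
        return f"1:{self.one_in_n_denominator()}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.numerator:g}:{self.denominator:g}"


# -- module-level aliases matching the functional surface ---------------------


def odds_from_risk(risk: float) -> Odds:
    return Odds.from_risk(risk)


def risk_from_odds(odds: Odds) -> float:
    return odds.risk


def apply_lr(odds: Odds, lr: float) -> Odds:
    return odds.times(lr)


def format_one_in_n(odds: Odds) -> str:
    return odds.one_in_n()


# -- metric <-> delta conversions ---------------------------------------------

_SQRT2 = math.sqrt(2.0)


def delta_from_metric(metric: ReportedMetric) -> RiskModel:
    """Convert a published metric to the standardized mean difference.

    ``delta = ln(value)`` for OR/HR per SD; ``delta = sqrt(2) * Phi^-1(value)``
    for AUC and C-index.
    """
    metric.check()
    if metric.kind in _RATIO_KINDS:
        delta = math.log(metric.value)
    else:
        delta = _SQRT2 * float(norm.ppf(metric.value))
    return RiskModel(delta)


def metric_from_delta(model: RiskModel, kind: MetricKind | str) -> float:
    """Exact inverse of :func:`delta_from_metric` for the given kind."""
    kind = MetricKind(kind)
    if kind in _RATIO_KINDS:
        return math.exp(model.delta)
    return float(norm.cdf(model.delta / _SQRT2))


def detection_rate(model: RiskModel, cut: ScreeningCut) -> float:
    """Fraction of affected individuals above the cut-off: 1 - Phi(z_cut - delta)."""
    return float(norm.sf(cut.z_cut - model.delta))


def required_delta_for_dr(target_dr: float, cut: ScreeningCut) -> RiskModel:
    """Delta solving ``detection_rate(delta, cut) == target_dr``.

    A target at or below the false positive rate yields a null or
    protective delta; the :class:`RiskModel` constructor flags the
    latter with a warning rather than raising.
    """
    if not 0.0 < target_dr < 1.0:
        raise ValidationError(f"target_dr must be in (0, 1), got {target_dr}")
    return RiskModel(cut.z_cut + float(norm.ppf(target_dr)))


def required_metric_for_dr(
    target_dr: float, cut: ScreeningCut, kind: MetricKind | str
) -> float:
    """Reported-metric value needed to reach ``target_dr`` at the cut's FPR."""
    return metric_from_delta(required_delta_for_dr(target_dr, cut), kind)
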