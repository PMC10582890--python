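"""Risk-factor screening arithmetic and two-stage screening flows.

Calculators for comparing screening strategies on whole-cohort counts:
detection and false positive rates recovered from 2x2 counts, events
prevented under a treatment model, the number needed to genotype to
prevent one additional event, and an integer-accounted two-stage screen
(score-based triage followed by a confirmatory test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from scipy.stats import norm

from .core import (
    Odds,
    RiskModel,
    ValidationError,
    round_half_away,
)

__all__ = [
    "InterventionModel",
    "NoIncrementalBenefitError",
    "ScreenCounts",
    "ScreenFlow",
    "events_prevented",
    "number_needed_to_genotype",
    "screening_metrics_from_counts",
    "treat_all_events_prevented",
    "two_stage_screen",
]


class NoIncrementalBenefitError(ValidationError):
    """The genotyped arm prevents no more events than the comparator."""


@dataclass(frozen=True)
class ScreenCounts:
    """Whole-cohort screening counts: who is flagged, who becomes affected."""

    n_total: int
    n_affected: int
    n_flagged: int
    n_affected_flagged: int

    def __post_init__(self) -> None:
        counts = (self.n_total, self.n_affected, self.n_flagged, self.n_affected_flagged)
        if any(c < 0 for c in counts):
            raise ValidationError(f"counts must be nonnegative, got {counts}")
        if self.n_affected_flagged > min(self.n_affected, self.n_flagged):
            raise ValidationError(
                "n_affected_flagged exceeds n_affected or n_flagged"
            )
        if max(self.n_affected, self.n_flagged) > self.n_total:
            raise ValidationError("component counts exceed n_total")


@dataclass(frozen=True)
class InterventionModel:
    """Treatment effect applied to flagged individuals."""

    relative_risk_reduction: float
    adherence: float = 1.0

    def __post_init__(self) -> None:
        for name in ("relative_risk_reduction", "adherence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def screening_metrics_from_counts(c: ScreenCounts) -> tuple[float, float]:
    """(detection rate, false positive rate) from cohort counts."""
    n_unaffected = c.n_total - c.n_affected
    if c.n_affected == 0 or n_unaffected == 0:
        raise ValidationError("need at least one affected and one unaffected person")
    dr = c.n_affected_flagged / c.n_affected
    fpr = (c.n_flagged - c.n_affected_flagged) / n_unaffected
    return dr, fpr


def events_prevented(events_above_cutoff: int, m: InterventionModel) -> int:
    """Whole events prevented among flagged individuals, rounded half away."""
    if events_above_cutoff < 0:
        raise ValidationError("events_above_cutoff must be nonnegative")
    return round_half_away(
        m.relative_risk_reduction * m.adherence * events_above_cutoff
    )


def treat_all_events_prevented(total_events: int, m: InterventionModel) -> int:
    """Events prevented if the whole cohort were treated."""
    return events_prevented(total_events, m)


def number_needed_to_genotype(
    cohort: int, prevented_with: float, prevented_without: float
) -> int:
    """People genotyped per additional event prevented.

    Printed per-arm prevented counts are rounded integers, and the
    difference of those rounded counts is the convention here; pass
    unrounded floats to get the unrounded alternative.
    """
    if cohort <= 0:
        raise ValidationError(f"cohort must be > 0, got {cohort}")
    gain = prevented_with - prevented_without
    if gain <= 0:
        raise NoIncrementalBenefitError(
            f"no incremental benefit: prevented_with={prevented_with} <= "
            f"prevented_without={prevented_without}"
        )
    return round_half_away(cohort / gain)


def nng_from_event_counts(
    cohort: int,
    events_above_cutoff_with: int,
    events_above_cutoff_without: int,
    m: InterventionModel,
    round_prevented: bool = True,
) -> int:
    """Number needed to genotype straight from per-arm event counts.

    ``round_prevented=True`` reproduces published arithmetic (per-arm
    prevented counts rounded before differencing); ``False`` differences
    the exact products.
    """
    effect = m.relative_risk_reduction * m.adherence
    if round_prevented:
        pw: float = events_prevented(events_above_cutoff_with, m)
        po: float = events_prevented(events_above_cutoff_without, m)
    else:
        pw = effect * events_above_cutoff_with
        po = effect * events_above_cutoff_without
    return number_needed_to_genotype(cohort, pw, po)


@dataclass(frozen=True)
class ScreenFlow:
    """Integer flow through a two-stage screen.

    Stage 1 flags the top scorers; stage 2 is a confirmatory test with
    its own detection and false positive rates applied only to stage-1
    positives.  Counts conserve the cohort exactly.
    """

    n_cohort: int
    n_affected: int
    n_unaffected: int
    stage1_affected_positive: int
    stage1_unaffected_positive: int
    stage2_detected: int
    stage2_missed: int
    stage2_false_positive: int
    missed_below_cutoff: int
    odds_given_stage1_positive: Odds

    def __post_init__(self) -> None:
        if self.n_affected + self.n_unaffected != self.n_cohort:
            raise ValidationError("affected + unaffected must equal cohort")
        if self.stage2_detected + self.stage2_missed != self.stage1_affected_positive:
            raise ValidationError("stage-2 split must cover stage-1 affected positives")
        if self.stage1_affected_positive + self.missed_below_cutoff != self.n_affected:
            raise ValidationError("affected flow does not conserve")
        if any(
            v < 0
            for v in (
                self.stage1_affected_positive,
                self.stage1_unaffected_positive,
                self.stage2_detected,
                self.stage2_missed,
                self.stage2_false_positive,
                self.missed_below_cutoff,
            )
        ):
            raise ValidationError("flow counts must be nonnegative")

    def as_dict(self) -> dict[str, object]:
        return {
            "n_cohort": self.n_cohort,
            "n_affected": self.n_affected,
            "n_unaffected": self.n_unaffected,
            "stage1_affected_positive": self.stage1_affected_positive,
            "stage1_unaffected_positive": self.stage1_unaffected_positive,
            "stage2_detected": self.stage2_detected,
            "stage2_missed": self.stage2_missed,
            "stage2_false_positive": self.stage2_false_positive,
            "missed_below_cutoff": self.missed_below_cutoff,
            "odds_given_stage1_positive": self.odds_given_stage1_positive.one_in_n(),
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_text(self) -> str:
        """A small text flow diagram."""
        return "\n".join(
            [
                f"cohort {self.n_cohort}",
                f"|- affected {self.n_affected}",
                f"|    |- stage-1 positive {self.stage1_affected_positive}",
                f"|    |    |- stage-2 detected {self.stage2_detected}",
                f"|    |    '- stage-2 missed   {self.stage2_missed}",
                f"|    '- below cut-off (missed) {self.missed_below_cutoff}",
                f"'- unaffected {self.n_unaffected}",
                f"     |- stage-1 positive {self.stage1_unaffected_positive}"
                f" (odds given positive {self.odds_given_stage1_positive.one_in_n()})",
                f"     '- stage-2 false positive {self.stage2_false_positive}",
            ]
        )


def two_stage_screen(
    n_cohort: int,
    background: Odds,
    stage1: tuple[RiskModel, float],
    stage2: tuple[float, float],
) -> ScreenFlow:
    """Push a cohort through score triage followed by a confirmatory test.

    Parameters
    ----------
    stage1 :
        ``(model, top_fraction)``: the score's mean difference and the
        flagged upper fraction of the unaffected distribution.
    stage2 :
        ``(dr, fpr)`` of the confirmatory test, applied to stage-1
        positives only.

    Counts round to the nearest integer at each branch; conservation is
    then enforced on the complementary branch of each split.
    """
    model, top_fraction = stage1
    stage2_dr, stage2_fpr = stage2
    if n_cohort <= 0:
        raise ValidationError(f"n_cohort must be > 0, got {n_cohort}")
    if not 0.0 < top_fraction < 1.0:
        raise ValidationError(f"top_fraction must be in (0, 1), got {top_fraction}")
    for name, v in (("stage-2 dr", stage2_dr), ("stage-2 fpr", stage2_fpr)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")

    n_affected = round_half_away(n_cohort * background.risk)
    n_unaffected = n_cohort - n_affected

    z_cut = float(norm.isf(top_fraction))
    dr_stage1 = float(norm.sf(z_cut - model.delta))
    aff_pos = round_half_away(n_affected * dr_stage1)
    unaff_pos = round_half_away(n_unaffected * top_fraction)
    detected = round_half_away(stage2_dr * aff_pos)

    return ScreenFlow(
        n_cohort=n_cohort,
        n_affected=n_affected,
        n_unaffected=n_unaffected,
        stage1_affected_positive=aff_pos,
        stage1_unaffected_positive=unaff_pos,
        stage2_detected=detected,
        stage2_missed=aff_pos - detected,
        stage2_false_positive=round_half_away(stage2_fpr * unaff_pos),
        missed_below_cutoff=n_affected - aff_pos,
        odds_given_stage1_positive=Odds(aff_pos, unaff_pos)
        if unaff_pos > 0
        else Odds(aff_pos, 1),
    )
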