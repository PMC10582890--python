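"""Shared fixtures: canonical models, cut-offs, and published count tables."""

import pytest

from prscreen.core import Odds, RiskModel, ScreeningCut

# Published whole-cohort screening counts used by the intervention tests
# (two studies, each with and without genotype information).
RISK_FACTOR_TABLE = {
    "study_a": {
        "cohort": 100_000,
        "events": 7_997,
        "without": {"flagged": 26_722, "events_above": 4_783},
        "with": {"flagged": 26_445, "events_above": 4_870},
        "printed": {
            "dr_pct": (60, 61),
            "fpr_pct": (24, 23),
            "prevented": (957, 974),
            "nng": 5_882,
        },
    },
    "study_b": {
        "cohort": 186_451,
        "events": 4_247,
        "without": {"flagged": 79_754, "events_above": 3_450},
        "with": {"flagged": 78_092, "events_above": 3_557},
        "printed": {
            "dr_pct": (81, 84),
            "fpr_pct": (42, 41),
            "prevented": (690, 711),
            "nng": 8_879,
        },
    },
}


@pytest.fixture
def cad_model() -> RiskModel:
    """Coronary-artery-disease example: mean shift 0.48 SD."""
    return RiskModel(0.48)


@pytest.fixture
def breast_model() -> RiskModel:
    """Breast-cancer example: mean shift 0.37 SD."""
    return RiskModel(0.37)


@pytest.fixture
def cut5() -> ScreeningCut:
    return ScreeningCut.from_fpr(0.05)


@pytest.fixture
def cad_odds() -> Odds:
    """Background 10-year odds of 1:19 (risk 5%)."""
    return Odds(1, 19)


@pytest.fixture
def breast_odds() -> Odds:
    """Background 10-year odds of 1:41."""
    return Odds(1, 41)
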