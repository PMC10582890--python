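"""Tests for the likelihood-ratio constructions and stratification calculators."""

import math
from statistics import NormalDist

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prscreen.core import Odds, RiskModel, ScreeningCut
from prscreen.estimators import (
    CentileQuery,
    QuantileGroup,
    allocate_counts,
    individual_odds,
    lr_at_centile,
    lr_positive,
    lr_quantile_group,
    odds_given_positive,
    stratification_table,
    tail_analysis,
    top_vs_bottom_odds_ratio,
)
from prscreen.simulate import CohortSpec, simulate_prs_cohort

_PHI = NormalDist()


class TestLrPositive:
    def test_cad(self, cad_model, cut5):
        assert lr_positive(cad_model, cut5) == pytest.approx(2.4, abs=0.05)

    def test_breast(self, breast_model, cut5):
        assert lr_positive(breast_model, cut5) == pytest.approx(2.0, abs=0.05)

    def test_null(self):
        for fpr in (0.01, 0.05, 0.2):
            assert lr_positive(RiskModel(0.0), ScreeningCut.from_fpr(fpr)) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_odds_given_positive_cad(self, cad_model, cut5, cad_odds):
        assert odds_given_positive(cad_model, cut5, cad_odds).one_in_n() == "1:8"


class TestLrAtCentile:
    def test_cad_97_5(self, cad_model):
        # oracle: density ratio from the stdlib normal quantile
        z = _PHI.inv_cdf(0.975)
        expected = math.exp(0.48 * z - 0.48**2 / 2)
        got = lr_at_centile(cad_model, CentileQuery.from_percent(97.5))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(2.283, abs=1e-3)

    def test_null(self):
        for c in (2.5, 25.0, 50.0, 97.5):
            assert lr_at_centile(RiskModel(0.0), CentileQuery.from_percent(c)) == 1.0

    @pytest.mark.parametrize("delta", [0.2, 0.48, 1.0])
    def test_median_centile(self, delta):
        got = lr_at_centile(RiskModel(delta), CentileQuery.from_percent(50))
        assert got == pytest.approx(math.exp(-(delta**2) / 2), abs=1e-12)

    @given(delta=st.floats(0.05, 2.0))
    def test_log_linear_in_z(self, delta):
        model = RiskModel(delta)
        qs = [CentileQuery.from_percent(p) for p in (10, 30, 70, 90)]
        logs = [math.log(lr_at_centile(model, q)) for q in qs]
        slopes = [
            (l2 - l1) / (q2.z - q1.z)
            for (l1, q1), (l2, q2) in zip(zip(logs, qs), zip(logs[1:], qs[1:]))
        ]
        for s in slopes:
            assert s == pytest.approx(delta, rel=1e-9)


class TestCentileQuery:
    def test_units_explicit(self):
        assert CentileQuery.from_percent(97.5).z == pytest.approx(
            CentileQuery.from_fraction(0.975).z
        )

    def test_bounds(self):
        from prscreen.core import ValidationError

        with pytest.raises(ValidationError):
            CentileQuery.from_percent(0.0)
        with pytest.raises(ValidationError):
            CentileQuery.from_percent(100.0)


class TestIndividualOdds:
    # Published centile odds: CAD at background 1:19, breast at 1:41.
    # The CAD 2.5th-centile cell carries a +/-1 printed-rounding tolerance.
    @pytest.mark.parametrize(
        "centile,expected,tolerance",
        [(2.5, 54, 1), (25.0, 29, 0), (75.0, 15, 0), (97.5, 8, 0)],
    )
    def test_cad_centiles(self, cad_model, cad_odds, centile, expected, tolerance):
        n = individual_odds(
            cad_model, CentileQuery.from_percent(centile), cad_odds
        ).one_in_n_denominator()
        assert abs(n - expected) <= tolerance

    @pytest.mark.parametrize(
        "centile,expected", [(2.5, 91), (25.0, 56), (75.0, 34), (97.5, 21)]
    )
    def test_breast_centiles(self, breast_model, breast_odds, centile, expected):
        n = individual_odds(
            breast_model, CentileQuery.from_percent(centile), breast_odds
        ).one_in_n_denominator()
        assert n == expected

    def test_null_leaves_odds_unchanged(self, cad_odds):
        post = individual_odds(
            RiskModel(0.0), CentileQuery.from_percent(30), cad_odds
        )
        assert post.ratio == pytest.approx(cad_odds.ratio, rel=1e-12)


class TestLrQuantileGroup:
    def test_cad_lowest_quintile(self, cad_model):
        z = _PHI.inv_cdf(0.2)
        expected = _PHI.cdf(z - 0.48) / 0.2
        got = lr_quantile_group(cad_model, QuantileGroup(0.0, 0.2))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.466, abs=1e-3)

    def test_cad_highest_quintile(self, cad_model):
        z = _PHI.inv_cdf(0.8)
        expected = (1 - _PHI.cdf(z - 0.48)) / 0.2
        got = lr_quantile_group(cad_model, QuantileGroup(0.8, 1.0))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(1.794, abs=1e-3)

    def test_null(self):
        for group in (QuantileGroup(0, 0.2), QuantileGroup(0.3, 0.7), QuantileGroup(0.9, 1)):
            assert lr_quantile_group(RiskModel(0.0), group) == pytest.approx(
                1.0, abs=1e-12
            )

    @pytest.mark.parametrize("delta", [0.2, 0.48, 1.0])
    @pytest.mark.parametrize("center", [0.1, 0.5, 0.9])
    def test_narrow_group_approaches_centile_lr(self, delta, center):
        eps = 1e-4
        model = RiskModel(delta)
        group_lr = lr_quantile_group(model, QuantileGroup(center - eps, center + eps))
        point_lr = lr_at_centile(model, CentileQuery.from_fraction(center))
        assert abs(group_lr - point_lr) < 1e-3 * point_lr

    @given(
        delta=st.floats(0, 2),
        cuts=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=6, unique=True),
    )
    @settings(max_examples=100)
    def test_partition_normalizes(self, delta, cuts):
        edges = [0.0] + sorted(cuts) + [1.0]
        model = RiskModel(delta)
        total = sum(
            (hi - lo) * lr_quantile_group(model, QuantileGroup(lo, hi))
            for lo, hi in zip(edges, edges[1:])
            if hi - lo > 0
        )
        assert abs(total - 1.0) < 1e-9


class TestStratificationTable:
    def test_cad_quintiles(self, cad_model, cad_odds):
        table = stratification_table(cad_model, 5, cad_odds, 100_000)
        denoms = [r.odds.one_in_n_denominator() for r in table.rows]
        assert denoms[0] == 41
        assert denoms[-1] == 11

    def test_breast_quintiles(self, breast_model, breast_odds):
        table = stratification_table(breast_model, 5, breast_odds, 100_000)
        denoms = [r.odds.one_in_n_denominator() for r in table.rows]
        assert abs(denoms[0] - 72) <= 1  # printed-rounding tolerance on this cell
        assert denoms[-1] == 26

    def test_null_uniform(self, cad_odds):
        table = stratification_table(RiskModel(0.0), 5, cad_odds, 100_000)
        counts = [r.n_affected for r in table.rows]
        assert max(counts) - min(counts) <= 1
        for r in table.rows:
            assert r.odds.ratio == pytest.approx(cad_odds.ratio, rel=1e-12)

    @given(
        delta=st.floats(0, 2),
        n_groups=st.integers(2, 10),
        population=st.integers(1, 10**6),
        risk=st.floats(0.001, 0.5),
    )
    @settings(max_examples=100)
    def test_counts_conserve(self, delta, n_groups, population, risk):
        table = stratification_table(
            RiskModel(delta), n_groups, Odds.from_risk(risk), population
        )
        assert table.n_affected_total + table.n_unaffected_total == population
        assert table.n_affected_total == round(population * risk)
        assert sum(r.share_of_cases for r in table.rows) == pytest.approx(1.0, abs=1e-9)
        if table.n_affected_total > 0:
            assert sum(table.count_shares()) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_columns(self, cad_model, cad_odds):
        frame = stratification_table(cad_model, 5, cad_odds, 100_000).to_dataframe()
        assert list(frame.columns) == [
            "group_lo",
            "group_hi",
            "lr",
            "odds_1_in_n",
            "n_affected",
            "n_unaffected",
            "share_of_cases",
        ]

    def test_serialization_round_trip(self, cad_model, cad_odds):
        import json

        table = stratification_table(cad_model, 5, cad_odds, 100_000)
        payload = json.loads(table.to_json())
        assert payload["population"] == 100_000
        assert len(payload["rows"]) == 5
        assert payload["rows"][0]["odds_1_in_n"] == 41


class TestAllocateCounts:
    @given(
        total=st.integers(0, 10**6),
        weights=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=12).filter(
            lambda w: sum(w) > 0.01
        ),
    )
    def test_exact_total_and_fairness(self, total, weights):
        alloc = allocate_counts(total, weights)
        assert sum(alloc) == total
        expected = [total * w / sum(weights) for w in weights]
        for got, exp in zip(alloc, expected):
            assert abs(got - exp) < 1.0 + 1e-9


class TestTails:
    def test_cad_top_2_5(self, cad_model, cad_odds):
        res = tail_analysis(cad_model, 0.025, cad_odds)
        assert res.odds.one_in_n() == "1:7"
        assert round(res.share_of_cases * 100) == 7

    def test_breast_top_2_5_share(self, breast_model, breast_odds):
        res = tail_analysis(breast_model, 0.025, breast_odds)
        assert round(res.share_of_cases * 100) == 6

    def test_null(self, cad_odds):
        res = tail_analysis(RiskModel(0.0), 0.1, cad_odds)
        assert res.share_of_cases == pytest.approx(0.1, abs=1e-12)
        assert res.odds.ratio == pytest.approx(cad_odds.ratio, rel=1e-12)

    @given(delta=st.floats(0, 2), fraction=st.floats(0.005, 0.5))
    def test_share_at_least_fraction(self, delta, fraction):
        res = tail_analysis(RiskModel(delta), fraction, Odds(1, 19))
        assert res.share_of_cases >= fraction - 1e-12


class TestTopVsBottom:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.01, 13), (0.05, 7), (0.10, 5), (0.20, 4), (0.25, 3)],
    )
    def test_cad_published_ratios(self, cad_model, fraction, expected):
        assert round(top_vs_bottom_odds_ratio(cad_model, fraction)) == expected

    def test_null(self):
        assert top_vs_bottom_odds_ratio(RiskModel(0.0), 0.1) == pytest.approx(1.0)

    def test_decreasing_in_fraction(self, cad_model):
        values = [
            top_vs_bottom_odds_ratio(cad_model, f) for f in (0.01, 0.05, 0.1, 0.2, 0.25)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_equals_ratio_of_tail_lrs(self, cad_model, cad_odds):
        f = 0.05
        top = tail_analysis(cad_model, f, cad_odds).lr
        bottom = lr_quantile_group(cad_model, QuantileGroup(0.0, f))
        assert top_vs_bottom_odds_ratio(cad_model, f) == pytest.approx(top / bottom)


class TestBayesConsistency:
    def test_empirical_ppv_matches_analytic_odds(self, cad_model, cut5):
        """Screen-positive PPV on a simulated cohort matches the closed form."""
        risk = 0.05
        cohort = simulate_prs_cohort(CohortSpec(n=10**6, delta=0.48, risk=risk, seed=7))
        positive = cohort.score > cut5.z_cut
        n_pos = int(positive.sum())
        ppv_hat = float(cohort.affected[positive].mean())

        analytic = odds_given_positive(cad_model, cut5, Odds.from_risk(risk)).risk
        mc_se = math.sqrt(analytic * (1 - analytic) / n_pos)
        assert abs(ppv_hat - analytic) < 3 * mc_se
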