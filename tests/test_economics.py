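"""Cost ledger arithmetic, revenue valuation and effect-size equivalences."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gqay import economics as econ
from gqay.economics import (
    EconomicRates,
    equivalent_diversity_change,
    fertilizer_increment_cost,
    hay_transfer_cost,
    management_switch_cost,
    management_switch_cost_euro,
    management_switch_ledger,
    reseeding_process_cost,
    revenue,
    round_euro,
    task_cost,
    welch_test,
)


class TestCostLedgers:
    def test_fertilizer_increment(self):
        assert fertilizer_increment_cost() == pytest.approx(165.12, abs=0.01)
        assert round_euro(fertilizer_increment_cost()) == 165
        assert fertilizer_increment_cost(0, 0, 0) == 0
        # halving all increments halves each linear branch
        assert fertilizer_increment_cost(50, 21.8, 41.5) == pytest.approx(
            fertilizer_increment_cost() / 2)

    def test_task_costs(self):
        assert task_cost(["fertilizing"]) == pytest.approx(8.575)
        assert task_cost(["cutting", "windrowing", "collecting"]) == pytest.approx(77.405)
        assert task_cost([]) == 0
        with pytest.raises(KeyError):
            task_cost(["ploughing"])

    def test_reseeding_process(self):
        assert round_euro(reseeding_process_cost()) == 12
        fuel_only = dataclasses.replace(EconomicRates(), labor_rate=0.0)
        assert reseeding_process_cost(fuel_only) == pytest.approx(3.405)
        labor_only = dataclasses.replace(EconomicRates(), fuel_price=0.0)
        assert reseeding_process_cost(labor_only) == pytest.approx(8.84)

    def test_hay_transfer_ledger(self):
        ledger = hay_transfer_cost()
        assert ledger.total == pytest.approx(426.535)
        assert ledger.total_euro == 427
        assert ledger.total == pytest.approx(sum(v for _, v in ledger.items))
        no_opp = dataclasses.replace(EconomicRates(), hay_opportunity_cost=0.0)
        assert hay_transfer_cost(no_opp).total_euro == 177
        double_labor = dataclasses.replace(EconomicRates(), labor_rate=26.0)
        extra = hay_transfer_cost(double_labor).total - ledger.total
        assert extra == pytest.approx(10.92 * 13)  # sum of chain hours x wage

    def test_cost_linearity_in_rates(self):
        base = EconomicRates()
        doubled = dataclasses.replace(
            base, labor_rate=2 * base.labor_rate, fuel_price=2 * base.fuel_price,
            can_price=2 * base.can_price, pk_price=2 * base.pk_price,
            hay_opportunity_cost=2 * base.hay_opportunity_cost,
        )
        assert hay_transfer_cost(doubled).total == pytest.approx(
            2 * hay_transfer_cost(base).total)
        assert fertilizer_increment_cost(rates=doubled) == pytest.approx(
            2 * fertilizer_increment_cost(rates=base))


class TestManagementSwitch:
    @pytest.mark.parametrize("a, b, expected", [
        ("less_intensive", "intensive", -174),
        ("less_intensive", "very_highly_intensive", -493),
    ])
    def test_reported_switch_costs(self, a, b, expected):
        assert management_switch_cost_euro(a, b) == expected

    def test_switch_to_self_is_free(self):
        assert management_switch_cost("intensive", "intensive") == 0.0

    def test_chain_additivity(self):
        direct = management_switch_cost("less_intensive", "very_highly_intensive")
        chained = (management_switch_cost("less_intensive", "intensive")
                   + management_switch_cost("intensive", "very_highly_intensive"))
        assert direct == pytest.approx(chained)

    def test_deintensification_is_symmetric_saving(self):
        down = management_switch_cost("very_highly_intensive", "less_intensive")
        up = management_switch_cost("less_intensive", "very_highly_intensive")
        assert down == pytest.approx(-up)

    def test_ledger_items_sum_to_total(self):
        ledger = management_switch_ledger("less_intensive", "very_highly_intensive")
        names = [n for n, _ in ledger.items]
        assert names == ["fertilizer_step_1", "fertilizer_step_2",
                         "fertilizer_application", "extra_cut_1", "extra_cut_2"]
        assert ledger.total == pytest.approx(sum(v for _, v in ledger.items))


class TestRevenue:
    @pytest.mark.parametrize("yield_m2, price, expected", [
        (0.0, 0.31, 0.0),
        (1.0, 0.31, 3100.0),
        (0.5, 0.40, 2000.0),
    ])
    def test_valuation(self, yield_m2, price, expected):
        rates = dataclasses.replace(EconomicRates(), milk_price=price)
        out = revenue(yield_m2, rates)
        assert out.revenue == pytest.approx(expected)
        assert out.milk_yield_ha == pytest.approx(yield_m2 * 1e4)

    def test_homogeneity_in_yield_and_price(self):
        base = revenue(0.7).revenue
        assert revenue(1.4).revenue == pytest.approx(2 * base)
        doubled = dataclasses.replace(EconomicRates(), milk_price=0.62)
        assert revenue(0.7, doubled).revenue == pytest.approx(2 * base)

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            revenue(-0.1)


class _StubFit:
    """Minimal fit interface for the closed-form equivalence check."""

    def __init__(self, slopes, predictions):
        self.diversity_slopes = pd.Series(slopes)
        self._pred = predictions

    def predict_grid(self, d_grid, managements=None, **kw):
        return pd.DataFrame([
            {"richness": d, "management": m, "predicted": self._pred[m]}
            for d in d_grid for m in managements
        ])


class TestEquivalentDiversity:
    def test_closed_form_inversion(self):
        fit = _StubFit({"less_intensive": 100.0},
                       {"less_intensive": 500.0, "intensive": 600.0})
        eq = equivalent_diversity_change(fit, "less_intensive", "intensive", 1.0)
        # gap 100 over slope 100: sqrt(D*) = 1 + 1 = 2 -> D* = 4
        assert eq.d_star == pytest.approx(4.0)
        assert eq.species_rounded == 4
        assert not eq.extrapolated

    def test_zero_gap_returns_start(self):
        fit = _StubFit({"less_intensive": 100.0},
                       {"less_intensive": 500.0, "intensive": 500.0})
        eq = equivalent_diversity_change(fit, "less_intensive", "intensive", 3.0)
        assert eq.d_star == pytest.approx(3.0)

    def test_gap_beyond_gradient_is_clipped_and_flagged(self):
        fit = _StubFit({"less_intensive": 10.0},
                       {"less_intensive": 0.0, "intensive": 1000.0})
        eq = equivalent_diversity_change(fit, "less_intensive", "intensive", 1.0)
        assert eq.d_star == 60.0 and eq.extrapolated

    def test_nonpositive_slope_reports_no_solution(self):
        fit = _StubFit({"less_intensive": -5.0},
                       {"less_intensive": 0.0, "intensive": 100.0})
        eq = equivalent_diversity_change(fit, "less_intensive", "intensive", 1.0)
        assert eq.no_solution and "slope" in eq.reason


class TestWelch:
    def test_identical_samples_give_zero_statistic(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_zero_variance_convention(self):
        t, df, p = welch_test([0, 0, 0, 0], [1, 1, 1, 1])
        assert np.isinf(t) and p == 0.0
        t, df, p = welch_test([2, 2], [2, 2])
        assert t == 0.0 and p == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(42)
        n_reject = 0
        reps = 4000
        for _ in range(reps):
            t, df, p = welch_test(rng.normal(size=15), rng.normal(0, 2, size=10))
            n_reject += p < 0.05
        assert 0.035 < n_reject / reps < 0.065
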