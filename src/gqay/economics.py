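"""Bioeconomic valuation of grassland management and diversity changes.

Revenues value the milk production potential yield of a sward at the farm
milk price:

    revenue (Euro ha^-1 a^-1) = milk potential yield (kg m^-2 a^-1) x 10^4
                                x milk price (Euro kg^-1)

Variable costs of changing management intensity are itemized from standard
machinery/labor cost accounting: fertilizer purchase (calcium ammonium
nitrate for N, a PK compound bought to cover the binding nutrient),
fertilizer application, and the cutting-windrowing-collecting chain per
extra cut.  Diversity restoration options are costed the same way
(reseeding process, seed-mixture purchase as a configured input, and fresh
hay transfer including opportunity cost of the donor site).

All ledgers are computed at full precision; totals are rounded half-up to
whole Euro only for display, matching conventional cost-table reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .experiment import ManagementRegime

__all__ = [
    "EconomicRates",
    "CostLedger",
    "RevenueResult",
    "EquivalentDiversity",
    "revenue",
    "fertilizer_increment_cost",
    "task_cost",
    "reseeding_process_cost",
    "hay_transfer_cost",
    "management_switch_ledger",
    "management_switch_cost",
    "management_switch_cost_euro",
    "equivalent_diversity_change",
    "welch_test",
    "round_euro",
]

#: machinery tasks: name -> (hours per ha, fuel litres per ha)
DEFAULT_TASKS: dict[str, tuple[float, float]] = {
    "fertilizing": (0.55, 1.9),
    "cutting": (0.67, 4.85),
    "windrowing": (0.53, 3.18),
    "collecting": (3.56, 12.67),
    "reseeding": (0.27, 2.08),
    "rolling": (0.41, 2.46),
    "hay_transport": (5.27, 19.74),
    "hay_distribution": (0.89, 5.66),
}

#: nutrient increments accompanying one 100 kg N ha^-1 fertilization step
N_STEP = 100.0   # kg N ha^-1
P_STEP = 43.6    # kg P ha^-1
K_STEP = 83.0    # kg K ha^-1


@dataclass(frozen=True)
class EconomicRates:
    """Prices, wage/fuel rates and task requirements for the cost model."""

    milk_price: float = 0.31            # Euro per kg milk
    labor_rate: float = 13.0            # Euro per hour
    fuel_price: float = 0.75            # Euro per litre
    can_n_fraction: float = 0.27        # kg N per kg calcium ammonium nitrate
    can_price: float = 0.23             # Euro per kg CAN
    pk_p_fraction: float = 0.12         # kg P per kg PK fertilizer
    pk_k_fraction: float = 0.24         # kg K per kg PK fertilizer
    pk_price: float = 0.22              # Euro per kg PK
    hay_opportunity_cost: float = 250.0  # Euro per ha donor-site compensation
    tasks: dict = field(default_factory=lambda: dict(DEFAULT_TASKS))
    # seed-mixture purchase prices (Euro/ha for 20 kg/ha reseeding); survey
    # means taken as configured inputs, not recomputed
    mixture_price_diverse: float = 1203.0
    mixture_price_standard_adjusted: float = 229.0
    mixture_price_standard: float = 104.0

    def __post_init__(self) -> None:
        for name in ("milk_price", "labor_rate", "fuel_price", "can_price",
                     "pk_price", "hay_opportunity_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("can_n_fraction", "pk_p_fraction", "pk_k_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def round_euro(x: float) -> int:
    """Round half-up to whole Euro (display/report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CostLedger:
    """Itemized variable costs (Euro ha^-1 a^-1)."""

    items: tuple[tuple[str, float], ...]

    @property
    def total(self) -> float:
        return sum(v for _, v in self.items)

    @property
    def total_euro(self) -> int:
        return round_euro(self.total)

    @property
    def total_euro_by_item(self) -> int:
        """Sum of per-item rounded values (conventional cost-table arithmetic)."""
        return sum(round_euro(v) for _, v in self.items)

    def as_dict(self) -> dict[str, float]:
        return dict(self.items)


@dataclass(frozen=True)
class RevenueResult:
    """Milk revenue of one management x diversity combination."""

    milk_yield_m2: float     # kg m^-2 a^-1
    milk_yield_ha: float     # kg ha^-1 a^-1
    revenue: float           # Euro ha^-1 a^-1
    management: str | None = None
    richness: float | None = None


def revenue(milk_yield_m2: float, rates: EconomicRates | None = None,
            management: str | None = None, richness: float | None = None
            ) -> RevenueResult:
    """Value a milk production potential yield (kg m^-2 a^-1) at the milk price."""
    rates = rates or EconomicRates()
    if milk_yield_m2 < 0:
        raise ValueError("milk yield must be >= 0")
    yield_ha = milk_yield_m2 * 1.0e4
    return RevenueResult(
        milk_yield_m2=milk_yield_m2,
        milk_yield_ha=yield_ha,
        revenue=yield_ha * rates.milk_price,
        management=management,
        richness=richness,
    )


def fertilizer_increment_cost(d_n: float = N_STEP, d_p: float = P_STEP,
                              d_k: float = K_STEP,
                              rates: EconomicRates | None = None) -> float:
    """Fertilizer purchase cost (Euro ha^-1 a^-1) of a nutrient increment.

    N is supplied as calcium ammonium nitrate; P and K come from one PK
    compound, bought in the amount that satisfies the binding nutrient
    (max of the two requirements).
    """
    rates = rates or EconomicRates()
    if min(d_n, d_p, d_k) < 0:
        raise ValueError("nutrient increments must be >= 0")
    can_kg = d_n / rates.can_n_fraction
    pk_kg = max(d_p / rates.pk_p_fraction, d_k / rates.pk_k_fraction)
    return can_kg * rates.can_price + pk_kg * rates.pk_price


def task_cost(tasks, rates: EconomicRates | None = None) -> float:
    """Labor + fuel cost (Euro ha^-1 a^-1) of a list of machinery tasks."""
    rates = rates or EconomicRates()
    total = 0.0
    for name in tasks:
        if name not in rates.tasks:
            raise KeyError(
                f"unknown task {name!r}; known tasks: {sorted(rates.tasks)}"
            )
        hours, fuel = rates.tasks[name]
        total += hours * rates.labor_rate + fuel * rates.fuel_price
    return total


def reseeding_process_cost(rates: EconomicRates | None = None) -> float:
    """Process cost of reseeding (reseeding pass + rolling), Euro ha^-1 a^-1."""
    return task_cost(["reseeding", "rolling"], rates)


def hay_transfer_cost(rates: EconomicRates | None = None) -> CostLedger:
    """Itemized variable cost of fresh hay transfer from a donor grassland.

    Work chain: cutting, windrowing, loading/transport, collecting and
    distributing the seed-containing hay, plus the opportunity cost
    (compensation) of the donor site.
    """
    rates = rates or EconomicRates()
    chain = ["cutting", "windrowing", "hay_transport", "collecting", "hay_distribution"]
    items = [(name, task_cost([name], rates)) for name in chain]
    items.append(("donor_site_opportunity_cost", rates.hay_opportunity_cost))
    return CostLedger(items=tuple(items))


def management_switch_ledger(from_regime: ManagementRegime | str,
                             to_regime: ManagementRegime | str,
                             rates: EconomicRates | None = None) -> CostLedger:
    """Itemized variable-cost change of switching management intensity.

    Intensification is charged per 100 kg N ha^-1 fertilization step
    (fertilizer purchase incl. the matching PK amounts), a one-off
    fertilizer-application process cost when moving from zero to nonzero
    fertilization, and the cutting chain per additional cut.  Items are
    positive costs; de-intensification yields the symmetric negative items,
    which makes the ledger additive along chains of switches.
    """
    rates = rates or EconomicRates()
    if isinstance(from_regime, str):
        from_regime = ManagementRegime.by_name(from_regime)
    if isinstance(to_regime, str):
        to_regime = ManagementRegime.by_name(to_regime)
    items: list[tuple[str, float]] = []
    n_steps = round((to_regime.n_fert - from_regime.n_fert) / N_STEP)
    step_cost = fertilizer_increment_cost(rates=rates)
    sign = 1 if n_steps >= 0 else -1
    for i in range(abs(n_steps)):
        items.append((f"fertilizer_step_{i + 1}", sign * step_cost))
    if from_regime.n_fert == 0 and to_regime.n_fert > 0:
        items.append(("fertilizer_application", task_cost(["fertilizing"], rates)))
    elif from_regime.n_fert > 0 and to_regime.n_fert == 0:
        items.append(("fertilizer_application", -task_cost(["fertilizing"], rates)))
    d_cuts = to_regime.cuts_per_year - from_regime.cuts_per_year
    cut_cost = task_cost(["cutting", "windrowing", "collecting"], rates)
    sign = 1 if d_cuts >= 0 else -1
    for i in range(abs(d_cuts)):
        items.append((f"extra_cut_{i + 1}", sign * cut_cost))
    return CostLedger(items=tuple(items))


def management_switch_cost(from_regime, to_regime,
                           rates: EconomicRates | None = None) -> float:
    """Full-precision profit change (Euro ha^-1 a^-1) of a management switch.

    Costs of intensification appear as a negative profit change (e.g. less
    intensive -> intensive gives -(165.12 + 8.58) = -173.70).
    """
    return -management_switch_ledger(from_regime, to_regime, rates).total


def management_switch_cost_euro(from_regime, to_regime,
                                rates: EconomicRates | None = None) -> int:
    """Reported whole-Euro profit change, summing per-item rounded costs.

    Cost tables conventionally round each item before summing (one
    fertilizer step 165, application 9, one cut 77), so a switch adding two
    steps, application and two cuts reports -(165x2 + 9 + 77x2) = -493.
    """
    return -management_switch_ledger(from_regime, to_regime, rates).total_euro_by_item


@dataclass(frozen=True)
class EquivalentDiversity:
    """Diversity change with the same predicted revenue effect as a
    management switch."""

    d_start: float
    d_star: float                 # solution, clipped to [1, 60]
    d_star_unclipped: float | None
    species_rounded: int | None
    revenue_gap: float            # Euro ha^-1 a^-1
    slope: float                  # Euro per sqrt-species unit
    extrapolated: bool
    no_solution: bool = False
    reason: str = ""


def equivalent_diversity_change(fit, m_base: str, m_target: str,
                                d_start: float = 1.0) -> EquivalentDiversity:
    """Diversity level D* in ``m_base`` matching the revenue of ``m_target``.

    Solves beta_{D x m_base} (sqrt(D*) - sqrt(D_start)) = revenue gap, where
    the gap is the fixed-effects predicted revenue difference between the
    target and base management at D_start.  ``fit`` must be a
    :class:`~gqay.diversity.DiversityResults` on a revenue response (Euro
    ha^-1 a^-1 scale).
    """
    if d_start < 1:
        raise ValueError("d_start must be >= 1")
    pred = fit.predict_grid([d_start], managements=[m_base, m_target])
    p = pred.set_index("management")["predicted"]
    gap = float(p[m_target] - p[m_base])
    slope = float(fit.diversity_slopes[m_base])
    if gap == 0.0:
        return EquivalentDiversity(
            d_start=d_start, d_star=float(d_start), d_star_unclipped=float(d_start),
            species_rounded=round(d_start), revenue_gap=0.0, slope=slope,
            extrapolated=False,
        )
    if slope <= 0:
        return EquivalentDiversity(
            d_start=d_start, d_star=np.nan, d_star_unclipped=None,
            species_rounded=None, revenue_gap=gap, slope=slope,
            extrapolated=False, no_solution=True,
            reason="non-positive diversity slope in base management",
        )
    sqrt_star = math.sqrt(d_start) + gap / slope
    if sqrt_star < 0:
        return EquivalentDiversity(
            d_start=d_start, d_star=1.0, d_star_unclipped=None,
            species_rounded=None, revenue_gap=gap, slope=slope,
            extrapolated=True, no_solution=True,
            reason="revenue gap more negative than any diversity reduction",
        )
    d_star = sqrt_star**2
    clipped = float(np.clip(d_star, 1.0, 60.0))
    return EquivalentDiversity(
        d_start=d_start, d_star=clipped, d_star_unclipped=d_star,
        species_rounded=round(d_star), revenue_gap=gap, slope=slope,
        extrapolated=not (1.0 <= d_star <= 60.0),
    )


def welch_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances): returns (t, df, p).

    Degenerate convention when both samples have zero variance: equal means
    give (0, n_a + n_b - 2, 1); unequal means give (inf signed, same df, 0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(t), float(df), float(p)
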