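"""Valuation of a cohort trace: costs, QALYs, ICERs and WHO classification.

Costs and QALYs accrue from the state occupied at the start of each 2-year
cycle (no half-cycle correction) and are discounted — costs at 7.2%/year,
QALYs at 3%/year by default — to the end of the cycle's first year.  The
incremental cost-effectiveness ratio (ICER) of each interferon-beta strategy
is taken against symptom management alone and classified against the WHO
GDP-per-capita multiples: highly cost-effective below 1x GDP per QALY,
cost-effective between 1x and 3x, not cost-effective above 3x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .markov import CohortTrace
from .parameters import ParameterSet, ProductSpec, ValidationError
from .states import HealthState

__all__ = [
    "COST_COMPONENTS",
    "CycleOutcome",
    "Totals",
    "CEResult",
    "discount_factor",
    "cycle_utility",
    "cycle_cost",
    "accumulate",
    "icer",
    "who_classify",
    "HIGHLY_COST_EFFECTIVE",
    "COST_EFFECTIVE",
    "NOT_COST_EFFECTIVE",
]

COST_COMPONENTS = (
    "drug",
    "other_direct_medical",
    "non_medical_direct",
    "indirect",
    "relapse",
)

HIGHLY_COST_EFFECTIVE = "highly cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"


def discount_factor(
    rate: float, cycle: int, convention: str = "first_year_end"
) -> float:
    """Present-value factor for flows of 2-year cycle ``cycle`` (1-based).

    The default convention discounts each cycle's flows to the end of the
    cycle's first year: ``(1+rate)^-(2t-1)``.  The ``cycle_end`` alternative
    uses ``(1+rate)^-2t``.
    """
    if rate < 0:
        raise ValidationError(f"discount rate {rate} must be >= 0")
    if cycle < 1:
        raise ValidationError(f"cycle {cycle} must be >= 1")
    if convention == "first_year_end":
        years = 2 * cycle - 1
    elif convention == "cycle_end":
        years = 2 * cycle
    else:
        raise ValidationError(f"unknown discount convention {convention!r}")
    return (1.0 + rate) ** -years


def cycle_utility(
    trace: CohortTrace,
    cycle: int,
    params: ParameterSet,
    instrument: str,
) -> float:
    """QALYs accrued during one cycle (undiscounted).

    Start-of-cycle occupancy x state utility x cycle length, minus expected
    relapses x per-relapse utility loss x episode duration; floored at zero.
    """
    us = params.utilities[instrument]
    cfg = params.config
    occ = trace.start_of_cycle(cycle)
    base = sum(
        occ[i] * us.state_utility(s.health)
        for i, s in enumerate(trace.space.states)
        if occ[i] > 0.0
    ) * cfg.cycle_length_years
    relapses = trace.relapses_rrms[cycle] + trace.relapses_spms[cycle]
    decrement = relapses * us.relapse_utility_loss * cfg.relapse_episode_duration_years
    return max(base - decrement, 0.0)


def cycle_cost(
    trace: CohortTrace,
    cycle: int,
    params: ParameterSet,
    strategy: ProductSpec | None,
) -> dict[str, float]:
    """Cost components accrued during one cycle (undiscounted, USD).

    Annual per-state costs are doubled per 2-year cycle and weighted by
    start-of-cycle occupancy.  Drug and NSAID costs apply only to
    on-treatment mass (interferon-eligible states), using the occupied
    status's product; antidepressants use the first-three-cycles row for
    cycles 1-3.  Relapse costs are expected relapses times the per-episode
    cost by MS type.
    """
    costs = params.costs
    cfg = params.config
    occ = trace.start_of_cycle(cycle)
    years = cfg.cycle_length_years
    out = {c: 0.0 for c in COST_COMPONENTS}
    for i, st in enumerate(trace.space.states):
        mass = occ[i]
        if mass == 0.0 or st.health is HealthState.DEATH:
            continue
        key = st.health.value
        if st.status.on_treatment:
            product = params.product(st.status.product_id)
            out["drug"] += mass * years * costs.drug[product.id][key]
            out["other_direct_medical"] += (
                mass * years * costs.nsaid[product.efficacy_class][key]
            )
        out["other_direct_medical"] += mass * years * (
            costs.symptomatic_cost(key, cycle)
            + sum(costs.other_direct_medical[key].values())
        )
        out["non_medical_direct"] += mass * years * sum(
            costs.non_medical_direct[key].values()
        )
        out["indirect"] += mass * years * sum(costs.indirect[key].values())
    out["relapse"] = (
        trace.relapses_rrms[cycle] * costs.relapse_cost["rrms"]
        + trace.relapses_spms[cycle] * costs.relapse_cost["spms"]
    )
    return out


@dataclass
class CycleOutcome:
    """Undiscounted and discounted flows of one cycle."""

    cycle: int
    cost_components: dict[str, float]
    qaly: float
    df_cost: float
    df_qaly: float

    @property
    def cost(self) -> float:
        return sum(self.cost_components.values())

    @property
    def cost_discounted(self) -> float:
        return self.cost * self.df_cost

    @property
    def qaly_discounted(self) -> float:
        return self.qaly * self.df_qaly


@dataclass
class Totals:
    """Horizon totals for one (strategy, instrument) pair."""

    strategy_id: str
    instrument: str
    cost: float
    qaly: float
    cost_discounted: float
    qaly_discounted: float
    cost_components: dict[str, float] = field(default_factory=dict)

    def select(self, discounted: bool) -> tuple[float, float]:
        if discounted:
            return self.cost_discounted, self.qaly_discounted
        return self.cost, self.qaly


def accumulate(
    trace: CohortTrace,
    params: ParameterSet,
    strategy: ProductSpec | None,
    instrument: str = "literature",
) -> tuple[list[CycleOutcome], Totals]:
    """Per-cycle outcomes and horizon totals for one strategy."""
    cfg = params.config
    outcomes = []
    for cycle in range(1, cfg.n_cycles + 1):
        comp = cycle_cost(trace, cycle, params, strategy)
        outcomes.append(
            CycleOutcome(
                cycle=cycle,
                cost_components=comp,
                qaly=cycle_utility(trace, cycle, params, instrument),
                df_cost=discount_factor(
                    cfg.discount_rate_cost, cycle, cfg.discount_convention
                ),
                df_qaly=discount_factor(
                    cfg.discount_rate_qaly, cycle, cfg.discount_convention
                ),
            )
        )
    totals = Totals(
        strategy_id=strategy.id if strategy is not None else "symptom_management",
        instrument=instrument,
        cost=sum(o.cost for o in outcomes),
        qaly=sum(o.qaly for o in outcomes),
        cost_discounted=sum(o.cost_discounted for o in outcomes),
        qaly_discounted=sum(o.qaly_discounted for o in outcomes),
        cost_components={
            c: sum(o.cost_components[c] for o in outcomes) for c in COST_COMPONENTS
        },
    )
    return outcomes, totals


@dataclass
class CEResult:
    """Incremental cost-effectiveness of one strategy vs symptom management."""

    strategy_id: str
    instrument: str
    discounted: bool
    cost: float
    qaly: float
    comparator_cost: float
    comparator_qaly: float
    incremental_cost: float
    incremental_qaly: float
    icer: float          # NaN when undefined (zero or negative QALY gain)
    dominance: str | None
    who_class: str | None

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy_id,
            "instrument": self.instrument,
            "discounted": self.discounted,
            "cost": self.cost,
            "qaly": self.qaly,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "who_class": self.who_class,
        }


def who_classify(icer_value: float, gdp: float) -> str:
    """WHO GDP-multiple class of a (non-negative) cost-per-QALY ratio.

    Boundaries fall into the milder category: exactly 1x GDP is
    cost-effective (not highly), exactly 3x GDP is still cost-effective.
    """
    if gdp <= 0:
        raise ValidationError("gdp must be > 0")
    if icer_value < gdp:
        return HIGHLY_COST_EFFECTIVE
    if icer_value <= 3.0 * gdp:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def icer(
    strategy_totals: Totals,
    comparator_totals: Totals,
    discounted: bool,
    gdp: float,
) -> CEResult:
    """Incremental cost per QALY gained vs the comparator.

    Returns an undefined-ICER result (NaN) with a dominance flag when the
    QALY gain is non-positive, and flags the strategy dominant when it gains
    QALYs at no extra cost.
    """
    s_cost, s_qaly = strategy_totals.select(discounted)
    c_cost, c_qaly = comparator_totals.select(discounted)
    d_cost = s_cost - c_cost
    d_qaly = s_qaly - c_qaly
    dominance = None
    value = float("nan")
    who = None
    if d_qaly > 0.0:
        if d_cost <= 0.0:
            dominance = "dominant"
            who = HIGHLY_COST_EFFECTIVE
        else:
            value = d_cost / d_qaly
            who = who_classify(value, gdp)
    elif d_qaly < 0.0 and d_cost >= 0.0:
        dominance = "dominated"
        who = NOT_COST_EFFECTIVE
    # d_qaly == 0 (or QALY loss at lower cost): ICER undefined, no dominance call
    return CEResult(
        strategy_id=strategy_totals.strategy_id,
        instrument=strategy_totals.instrument,
        discounted=discounted,
        cost=s_cost,
        qaly=s_qaly,
        comparator_cost=c_cost,
        comparator_qaly=c_qaly,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=value,
        dominance=dominance,
        who_class=who,
    )


def outcomes_frame(outcomes: list[CycleOutcome]) -> pd.DataFrame:
    """Per-cycle outcome table (one row per cycle)."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "cycle": o.cycle,
                **{f"cost_{k}": v for k, v in o.cost_components.items()},
                "cost": o.cost,
                "qaly": o.qaly,
                "df_cost": o.df_cost,
                "df_qaly": o.df_qaly,
                "cost_discounted": o.cost_discounted,
                "qaly_discounted": o.qaly_discounted,
            }
        )
    return pd.DataFrame(rows)
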