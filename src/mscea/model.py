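"""Model / results objects wrapping the cohort engine and valuation rules.

``MarkovCohortModel`` is built from a validated :class:`ParameterSet` and a
strategy (a product id, or ``None`` for symptom management alone); ``run()``
returns a :class:`CohortResults` carrying the occupancy trace, per-cycle
outcomes, horizon totals and a ``summary()`` table, with
``compare_to(comparator)`` producing the incremental cost-effectiveness
result.
"""

from __future__ import annotations

import io

import pandas as pd

from . import outcomes as _outcomes
from .markov import CohortTrace, StateSpace, build_transition_matrix, run_cohort
from .outcomes import CEResult, CycleOutcome, Totals, accumulate, icer, outcomes_frame
from .parameters import INSTRUMENTS, ParameterSet, ProductSpec

__all__ = ["MarkovCohortModel", "CohortResults"]


class MarkovCohortModel:
    """Deterministic Markov cohort model for one treatment strategy.

    Parameters
    ----------
    params :
        Validated parameter bundle.
    strategy :
        Product id of the interferon-beta strategy, a :class:`ProductSpec`,
        or ``None`` for the symptom-management comparator.
    switching_enabled :
        When ``False`` the state space has no switched statuses and every
        withdrawal discontinues treatment (structural no-switching variant).
    """

    def __init__(
        self,
        params: ParameterSet,
        strategy: str | ProductSpec | None = None,
        switching_enabled: bool = True,
    ) -> None:
        self.params = params
        if isinstance(strategy, str):
            strategy = params.product(strategy)
        self.strategy = strategy
        self.switching_enabled = switching_enabled
        self.space = StateSpace.for_strategy(params, strategy, switching_enabled)

    @property
    def strategy_id(self) -> str:
        return self.strategy.id if self.strategy is not None else "symptom_management"

    def transition_matrix(self, cycle: int):
        return build_transition_matrix(cycle, self.params, self.strategy, self.space)

    def run(self) -> "CohortResults":
        trace = run_cohort(self.params, self.strategy, self.switching_enabled)
        return CohortResults(self, trace)


class CohortResults:
    """Results of one cohort projection.

    Valuation (costs/QALYs) is computed lazily per utility instrument and
    cached; the trace itself is strategy-level and instrument-independent.
    """

    def __init__(self, model: MarkovCohortModel, trace: CohortTrace) -> None:
        self.model = model
        self.trace = trace
        self._cache: dict[str, tuple[list[CycleOutcome], Totals]] = {}

    @property
    def params(self) -> ParameterSet:
        return self.model.params

    @property
    def strategy_id(self) -> str:
        return self.model.strategy_id

    def outcomes(self, instrument: str = "literature") -> tuple[list[CycleOutcome], Totals]:
        if instrument not in self._cache:
            self._cache[instrument] = accumulate(
                self.trace, self.params, self.model.strategy, instrument
            )
        return self._cache[instrument]

    def totals(self, instrument: str = "literature") -> Totals:
        return self.outcomes(instrument)[1]

    def cycle_frame(self, instrument: str = "literature") -> pd.DataFrame:
        return outcomes_frame(self.outcomes(instrument)[0])

    def compare_to(
        self,
        comparator: "CohortResults",
        instrument: str = "literature",
        discounted: bool = True,
    ) -> CEResult:
        """Incremental cost-effectiveness vs a comparator run (same params)."""
        return icer(
            self.totals(instrument),
            comparator.totals(instrument),
            discounted,
            self.params.config.gdp_per_capita,
        )

    def summary(self, instruments: tuple[str, ...] = INSTRUMENTS) -> str:
        """Human-readable run summary: occupancy milestones and totals."""
        buf = io.StringIO()
        health = self.trace.health_occupancy()
        buf.write(f"Strategy: {self.strategy_id}\n")
        buf.write(
            f"Horizon: {self.params.config.n_cycles} cycles of "
            f"{self.params.config.cycle_length_years:g} years, cohort age "
            f"{self.params.config.start_age:g} at entry\n"
        )
        buf.write(f"Surviving fraction at horizon: {1 - health['death'].iloc[-1]:.4f}\n")
        buf.write(
            f"Expected relapses over horizon: "
            f"{(self.trace.relapses_rrms.sum() + self.trace.relapses_spms.sum()):.3f}\n\n"
        )
        rows = []
        for inst in instruments:
            t = self.totals(inst)
            rows.append(
                {
                    "instrument": inst,
                    "cost": round(t.cost, 2),
                    "qaly": round(t.qaly, 4),
                    "cost_discounted": round(t.cost_discounted, 2),
                    "qaly_discounted": round(t.qaly_discounted, 4),
                }
            )
        buf.write(pd.DataFrame(rows).to_string(index=False))
        buf.write("\n")
        return buf.getvalue()

    def __repr__(self) -> str:
        return f"<CohortResults strategy={self.strategy_id!r}>"
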