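"""Deterministic cohort projection over the expanded (health, treatment) space.

Each 2-year cycle composes three event layers in a fixed order, each
conditional on the previous one:

1. death, with the age-band probability of the mortality table;
2. conditional on survival, withdrawal from the current product (resolved by
   the switching decision tree into switch / discontinue destinations);
3. conditional on the post-resolution treatment status, EDSS / SPMS
   progression under that status's efficacy class, with RRMS-to-SPMS
   transitions gated off before cycle 3.  Residual mass stays in place.

Mass progressing into an EDSS > 6 band loses treatment (those states carry
off-treatment status only).  The cohort starts with all mass in RRMS EDSS
1-3.5 on the assigned product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    NATURAL_HISTORY,
    ParameterSet,
    ProductSpec,
    TransitionParams,
    ValidationError,
)
from .states import (
    LIVING_STATES,
    OFF_TREATMENT,
    HealthState,
    ModelState,
    StatusKind,
    TreatmentStatus,
)
from .switching import resolve_withdrawal

__all__ = [
    "StateSpace",
    "CohortTrace",
    "progression_distribution",
    "compose_row",
    "build_transition_matrix",
    "run_cohort",
]

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class StateSpace:
    """Ordered (health, status) states for one strategy.

    For an active strategy the interferon-eligible health states carry the
    on-initial-product status, one switched status per permitted alternative,
    and off-treatment; severe-band states and Death carry off-treatment only.
    Symptom management has no on-treatment statuses at all.
    """

    states: tuple[ModelState, ...]
    switching_enabled: bool = True

    @classmethod
    def for_strategy(
        cls,
        params: ParameterSet,
        strategy: ProductSpec | None,
        switching_enabled: bool = True,
    ) -> "StateSpace":
        statuses: list[TreatmentStatus] = []
        if strategy is not None:
            statuses.append(TreatmentStatus(StatusKind.INITIAL, strategy.id))
            if switching_enabled:
                targets, _, _ = params.switching.split.get(strategy.id, ((), (), 1.0))
                statuses.extend(
                    TreatmentStatus(StatusKind.SWITCHED, t) for t in targets
                )
        statuses.append(OFF_TREATMENT)
        states = []
        for h in LIVING_STATES:
            if h.ifn_eligible:
                states.extend(ModelState(h, s) for s in statuses)
            else:
                states.append(ModelState(h, OFF_TREATMENT))
        states.append(ModelState(HealthState.DEATH, OFF_TREATMENT))
        return cls(states=tuple(states), switching_enabled=switching_enabled)

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: ModelState) -> int:
        return self.states.index(state)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def health_mask(self, health: HealthState) -> np.ndarray:
        return np.array([s.health is health for s in self.states])


def progression_distribution(
    health: HealthState, tp: TransitionParams, cycle: int
) -> dict[HealthState, float]:
    """Health-state movement during one cycle under one efficacy class.

    RRMS-to-SPMS conversion is forced to zero for cycles 1-2; disability
    never improves and SPMS never reverts to RRMS.
    """
    spms_open = cycle >= 3
    if health is HealthState.RRMS_MILD:
        moves = {HealthState.RRMS_MOD: tp.p_rrms_mild_to_mod}
    elif health is HealthState.RRMS_MOD:
        moves = {
            HealthState.RRMS_SEV: tp.p_rrms_mod_to_sev,
            HealthState.SPMS_MOD: tp.p_rrms_mod_to_spms_mod if spms_open else 0.0,
        }
    elif health is HealthState.RRMS_SEV:
        moves = {
            HealthState.SPMS_SEV: tp.p_rrms_sev_to_spms_sev if spms_open else 0.0
        }
    elif health is HealthState.SPMS_MOD:
        moves = {HealthState.SPMS_SEV: tp.p_spms_mod_to_sev}
    elif health is HealthState.SPMS_SEV:
        moves = {}
    else:
        raise ValidationError("Death has no progression distribution")
    total = sum(moves.values())
    if total > 1.0 + 1e-12:
        raise ValidationError(
            f"progression probabilities from {health.value} under "
            f"{tp.efficacy_class} exceed 1 ({total})"
        )
    dist = {dest: p for dest, p in moves.items() if p > 0.0}
    dist[health] = 1.0 - total
    return dist


def _destination(health: HealthState, status: TreatmentStatus) -> ModelState:
    # mass progressing beyond EDSS 6 loses treatment eligibility
    if status.on_treatment and not health.ifn_eligible:
        return ModelState(health, OFF_TREATMENT)
    return ModelState(health, status)


def compose_row(
    health: HealthState,
    status: TreatmentStatus,
    cycle: int,
    params: ParameterSet,
    strategy: ProductSpec | None,
    space: StateSpace,
) -> np.ndarray:
    """One transition-matrix row: death, then withdrawal, then progression."""
    cfg = params.config
    if not (1 <= cycle <= cfg.n_cycles):
        raise ValidationError(f"cycle {cycle} outside 1..{cfg.n_cycles}")
    state = ModelState(health, status)  # validates the combination
    row = np.zeros(len(space))
    if health is HealthState.DEATH:
        row[space.index(state)] = 1.0
        return row

    q = params.mortality.death_prob(
        cfg.age_at_cycle_start(cycle),
        cfg.mortality_interpretation,
        cfg.cycle_length_years,
    )
    row[space.index(ModelState(HealthState.DEATH, OFF_TREATMENT))] += q
    survive = 1.0 - q

    # survival layer: withdrawal resolution -> post-resolution statuses
    if status.on_treatment:
        product = params.product(status.product_id)
        tp = params.transition(product.efficacy_class)
        w = tp.withdrawal_prob(health, cycle)
        branches: list[tuple[TreatmentStatus, float]] = [(status, survive * (1.0 - w))]
        if w > 0.0:
            if space.switching_enabled:
                res = resolve_withdrawal(
                    product, health, cycle, params.switching, status.ever_switched
                )
                outcomes = res.outcomes
            else:  # structural no-switching variant: withdrawal = discontinuation
                outcomes = ((OFF_TREATMENT, 1.0),)
            for dest_status, p in outcomes:
                branches.append((dest_status, survive * w * p))
    else:
        branches = [(status, survive)]

    # progression layer under the post-resolution efficacy class
    for dest_status, mass in branches:
        if mass == 0.0:
            continue
        if dest_status.on_treatment:
            tp_dest = params.transition(
                params.product(dest_status.product_id).efficacy_class
            )
        else:
            tp_dest = params.natural_history
        for dest_health, p in progression_distribution(health, tp_dest, cycle).items():
            row[space.index(_destination(dest_health, dest_status))] += mass * p

    total = row.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(
            f"row for {state.label} at cycle {cycle} sums to {total!r}"
        )
    return row


def build_transition_matrix(
    cycle: int,
    params: ParameterSet,
    strategy: ProductSpec | None,
    space: StateSpace | None = None,
) -> np.ndarray:
    """Row-stochastic transition matrix over the strategy's state space."""
    if space is None:
        space = StateSpace.for_strategy(params, strategy)
    mat = np.vstack(
        [
            compose_row(s.health, s.status, cycle, params, strategy, space)
            for s in space.states
        ]
    )
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValidationError(f"transition matrix at cycle {cycle} not row-stochastic")
    return mat


@dataclass
class CohortTrace:
    """Occupancy fractions and per-cycle expected relapses over the horizon.

    ``occupancy[t]`` is the distribution over the state space at the start of
    cycle ``t + 1`` (row 0 is the initial condition; the last row is the end
    of the horizon).  ``relapses_rrms[t]`` / ``relapses_spms[t]`` hold the
    expected relapse count accrued during cycle ``t`` (index 0 unused), based
    on start-of-cycle occupancy and the occupant's efficacy class.
    """

    space: StateSpace
    occupancy: np.ndarray
    relapses_rrms: np.ndarray
    relapses_spms: np.ndarray
    ages: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def start_of_cycle(self, cycle: int) -> np.ndarray:
        """Occupancy at the start of cycle ``cycle`` (1-based)."""
        return self.occupancy[cycle - 1]

    def health_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated over treatment statuses (cycle x health state)."""
        data = {
            h.value: self.occupancy[:, self.space.health_mask(h)].sum(axis=1)
            for h in HealthState
        }
        return pd.DataFrame(data, index=pd.RangeIndex(len(self.occupancy), name="cycle"))

    def to_frame(self) -> pd.DataFrame:
        """Full occupancy trace, one column per (health, status) state."""
        return pd.DataFrame(
            self.occupancy,
            columns=self.space.labels,
            index=pd.RangeIndex(len(self.occupancy), name="cycle"),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (cycle, state, occupancy) export."""
        wide = self.to_frame().reset_index()
        return wide.melt(id_vars="cycle", var_name="state", value_name="occupancy")


def run_cohort(
    params: ParameterSet,
    strategy: ProductSpec | None,
    switching_enabled: bool = True,
) -> CohortTrace:
    """Project the cohort through all cycles for one strategy.

    All mass starts in RRMS EDSS 1-3.5, on the strategy's product (or off
    treatment for symptom management).
    """
    cfg = params.config
    space = StateSpace.for_strategy(params, strategy, switching_enabled)
    start_status = (
        TreatmentStatus(StatusKind.INITIAL, strategy.id)
        if strategy is not None
        else OFF_TREATMENT
    )
    start = space.index(ModelState(HealthState.RRMS_MILD, start_status))

    n = cfg.n_cycles
    occupancy = np.zeros((n + 1, len(space)))
    occupancy[0, start] = 1.0
    relapses_rrms = np.zeros(n + 1)
    relapses_spms = np.zeros(n + 1)
    ages = np.array([cfg.start_age + t * cfg.cycle_length_years for t in range(n + 1)])

    for cycle in range(1, n + 1):
        occ = occupancy[cycle - 1]
        # expected relapses during this cycle, from start-of-cycle occupancy
        for idx, st in enumerate(space.states):
            if occ[idx] == 0.0 or not st.health.is_alive:
                continue
            tp = (
                params.transition(
                    params.product(st.status.product_id).efficacy_class
                )
                if st.status.on_treatment
                else params.natural_history
            )
            rate = tp.relapse_rate(st.health, cycle)
            if st.health.ms_type == "rrms":
                relapses_rrms[cycle] += occ[idx] * rate
            else:
                relapses_spms[cycle] += occ[idx] * rate
        mat = build_transition_matrix(cycle, params, strategy, space)
        # sequential accumulation (not BLAS matmul): zero-mass compartments
        # then contribute exactly nothing, so structurally reduced variants
        # (e.g. switching disabled) propagate bitwise-identically
        nxt = np.zeros(len(space))
        for i in range(len(space)):
            if occ[i] != 0.0:
                nxt += occ[i] * mat[i]
        occupancy[cycle] = nxt

    return CohortTrace(
        space=space,
        occupancy=occupancy,
        relapses_rrms=relapses_rrms,
        relapses_spms=relapses_spms,
        ages=ages,
    )
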