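"""Transition-matrix composition and the deterministic cohort projection."""

import numpy as np
import pytest

from mscea import MarkovCohortModel, ValidationError
from mscea.markov import (
    StateSpace,
    build_transition_matrix,
    compose_row,
    progression_distribution,
    run_cohort,
)
from mscea.states import (
    OFF_TREATMENT,
    HealthState,
    ModelState,
    StatusKind,
    TreatmentStatus,
)

from conftest import ALL_STRATEGIES


@pytest.fixture()
def no_mortality(fresh_params):
    fresh_params.mortality.bands = [
        (lo, hi, 0.0) for lo, hi, _ in fresh_params.mortality.bands
    ]
    return fresh_params


class TestComposeRow:
    def test_natural_history_mild_row(self, no_mortality):
        """Untreated mild RRMS: 0.4 to the moderate band, 0.6 stays."""
        space = StateSpace.for_strategy(no_mortality, None)
        row = compose_row(
            HealthState.RRMS_MILD, OFF_TREATMENT, 1, no_mortality, None, space
        )
        assert row[space.index(ModelState(HealthState.RRMS_MOD, OFF_TREATMENT))] == 0.4
        assert row[space.index(ModelState(HealthState.RRMS_MILD, OFF_TREATMENT))] == 0.6
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_spms_gate_closed_before_cycle_three(self, no_mortality):
        """In cycles 1-2 no RRMS mass may convert to SPMS."""
        space = StateSpace.for_strategy(no_mortality, None)
        row = compose_row(
            HealthState.RRMS_MOD, OFF_TREATMENT, 1, no_mortality, None, space
        )
        assert row[space.index(ModelState(HealthState.SPMS_MOD, OFF_TREATMENT))] == 0.0
        assert row[space.index(ModelState(HealthState.RRMS_SEV, OFF_TREATMENT))] == 0.27
        assert row[space.index(ModelState(HealthState.RRMS_MOD, OFF_TREATMENT))] == pytest.approx(0.73)

    def test_spms_gate_open_from_cycle_three(self, no_mortality):
        space = StateSpace.for_strategy(no_mortality, None)
        row = compose_row(
            HealthState.RRMS_MOD, OFF_TREATMENT, 3, no_mortality, None, space
        )
        assert row[space.index(ModelState(HealthState.SPMS_MOD, OFF_TREATMENT))] == 0.43

    def test_death_is_absorbing(self, params):
        space = StateSpace.for_strategy(params, None)
        for cycle in (1, 8, 15):
            row = compose_row(
                HealthState.DEATH, OFF_TREATMENT, cycle, params, None, space
            )
            assert row[space.index(ModelState(HealthState.DEATH, OFF_TREATMENT))] == 1.0

    def test_progression_past_edss6_strips_treatment(self, no_mortality):
        strategy = no_mortality.product("rebif")
        space = StateSpace.for_strategy(no_mortality, strategy)
        status = TreatmentStatus(StatusKind.INITIAL, "rebif")
        row = compose_row(
            HealthState.RRMS_MOD, status, 1, no_mortality, strategy, space
        )
        # the severe band exists only with off-treatment status
        sev = row[space.index(ModelState(HealthState.RRMS_SEV, OFF_TREATMENT))]
        assert sev > 0.0

    def test_invalid_state_status_combination_rejected(self, params):
        with pytest.raises(ValueError, match="eligible"):
            ModelState(
                HealthState.RRMS_SEV, TreatmentStatus(StatusKind.INITIAL, "rebif")
            )

    def test_cycle_out_of_range_rejected(self, params):
        space = StateSpace.for_strategy(params, None)
        with pytest.raises(ValidationError, match="cycle"):
            compose_row(HealthState.RRMS_MILD, OFF_TREATMENT, 16, params, None, space)


class TestTransitionMatrix:
    @pytest.mark.parametrize("sid", ALL_STRATEGIES)
    @pytest.mark.parametrize("cycle", [1, 2, 3, 9, 15])
    def test_rows_sum_to_one(self, params, sid, cycle):
        strategy = params.product(sid) if sid else None
        mat = build_transition_matrix(cycle, params, strategy)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        assert (mat >= 0.0).all() and (mat <= 1.0).all()

    def test_symptom_management_matrix_static_after_gate(self, no_mortality):
        """With mortality ageing removed, the comparator's matrix is the
        same for every cycle from 3 on (only the SPMS gate and the age band
        vary with time)."""
        mats = [
            build_transition_matrix(c, no_mortality, None) for c in range(3, 16)
        ]
        for m in mats[1:]:
            assert np.array_equal(m, mats[0])

    def test_no_spms_to_rrms_or_improvement_transitions(self, params):
        strategy = params.product("betaferon")
        space = StateSpace.for_strategy(params, strategy)
        severity = {
            HealthState.RRMS_MILD: 0,
            HealthState.RRMS_MOD: 1,
            HealthState.RRMS_SEV: 2,
            HealthState.SPMS_MOD: 3,
            HealthState.SPMS_SEV: 4,
            HealthState.DEATH: 5,
        }
        rrms = {HealthState.RRMS_MILD, HealthState.RRMS_MOD, HealthState.RRMS_SEV}
        for cycle in (1, 5, 15):
            mat = build_transition_matrix(cycle, params, strategy, space)
            for i, src in enumerate(space.states):
                for j, dst in enumerate(space.states):
                    if mat[i, j] == 0.0:
                        continue
                    if dst.health in rrms:
                        assert src.health in rrms, (src, dst)
                    if dst.health is not HealthState.DEATH:
                        assert severity[dst.health] >= severity[src.health]


class TestCohortTrace:
    def test_initial_condition(self, cohort_results):
        for sid, res in cohort_results.items():
            occ0 = res.trace.occupancy[0]
            start = np.argmax(occ0)
            assert occ0[start] == 1.0
            assert occ0.sum() == 1.0
            assert res.trace.space.states[start].health is HealthState.RRMS_MILD

    def test_occupancy_conserved_every_cycle(self, cohort_results):
        for res in cohort_results.values():
            sums = res.trace.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_death_mass_non_decreasing(self, cohort_results):
        for res in cohort_results.values():
            death = res.trace.health_occupancy()["death"].to_numpy()
            assert (np.diff(death) >= -1e-15).all()

    def test_off_treatment_mass_non_decreasing_after_switch_window(
        self, cohort_results
    ):
        """After cycle 3 no switching and no reinitiation exist, so mass on
        treatment can only shrink."""
        for sid, res in cohort_results.items():
            if sid is None:
                continue
            on = np.array(
                [st.status.on_treatment for st in res.trace.space.states]
            )
            on_mass = res.trace.occupancy[:, on].sum(axis=1)
            assert (np.diff(on_mass[3:]) <= 1e-15).all()

    def test_state_space_has_no_forbidden_combinations(self, cohort_results):
        for res in cohort_results.values():
            for st in res.trace.space.states:
                if st.status.on_treatment:
                    assert st.health.ifn_eligible

    def test_switched_statuses_only_populated_in_switch_window_aftermath(
        self, cohort_results
    ):
        """Switched mass first appears after cycle 1 and stops growing after
        the 3-cycle window closes."""
        res = cohort_results["avonex"]
        switched = np.array(
            [st.status.ever_switched for st in res.trace.space.states]
        )
        sw_mass = res.trace.occupancy[:, switched].sum(axis=1)
        assert sw_mass[0] == 0.0
        assert sw_mass[1] > 0.0

    def test_trace_frames_shapes(self, cohort_results):
        res = cohort_results["rebif"]
        wide = res.trace.to_frame()
        assert wide.shape == (16, len(res.trace.space))
        long = res.trace.to_long_frame()
        assert len(long) == 16 * len(res.trace.space)
        health = res.trace.health_occupancy()
        assert np.allclose(health.sum(axis=1), 1.0)


class TestStrategyNeutralityLimit:
    def test_null_treatment_equals_symptom_management(self, fresh_params):
        """A product with natural-history efficacy, no withdrawal and zero
        drug/NSAID cost is indistinguishable from symptom management."""
        p = fresh_params
        nh = p.natural_history
        tp = p.transitions["im_ifnb1a"]
        for f in (
            *type(tp)._PROGRESSION_FIELDS,
            *type(tp)._RELAPSE_FIELDS,
        ):
            setattr(tp, f, getattr(nh, f))
        tp.withdrawal = {k: 0.0 for k in tp.withdrawal}
        for key in p.costs.drug["avonex"]:
            p.costs.drug["avonex"][key] = 0.0
        p.costs.nsaid["im_ifnb1a"] = {k: 0.0 for k in p.costs.nsaid["im_ifnb1a"]}
        p.product("avonex").annual_drug_cost = 0.0
        p.validate()

        sm = MarkovCohortModel(p, None).run()
        null = MarkovCohortModel(p, "avonex").run()
        assert np.allclose(
            null.trace.health_occupancy().to_numpy(),
            sm.trace.health_occupancy().to_numpy(),
            atol=1e-14,
        )
        for inst in ("literature", "hui3"):
            ts, tn = sm.totals(inst), null.totals(inst)
            assert tn.cost == pytest.approx(ts.cost, rel=1e-12)
            assert tn.qaly == pytest.approx(ts.qaly, rel=1e-12)
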