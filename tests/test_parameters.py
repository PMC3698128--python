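"""Parameter loading, validation, and the bundled default inputs."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscea import (
    ValidationError,
    default_parameters,
    load_parameters,
    save_parameters,
    weighted_drug_cost,
)
from mscea.parameters import (
    ModelConfig,
    MortalityTable,
    ParameterFormatError,
    SwitchingPolicy,
    TransitionParams,
    UtilitySet,
    WITHDRAWAL_KEYS,
)


class TestDefaultBundle:
    def test_natural_history_progression_values(self, params):
        nh = params.natural_history
        assert nh.p_rrms_mild_to_mod == 0.4
        assert nh.p_rrms_mod_to_sev == 0.27
        assert nh.p_rrms_mod_to_spms_mod == 0.43
        assert nh.p_rrms_sev_to_spms_sev == 0.31
        assert nh.p_spms_mod_to_sev == 0.5
        assert nh.withdrawal == {}

    @pytest.mark.parametrize(
        "cls,field,expected",
        [
            ("im_ifnb1a", "p_rrms_mild_to_mod", 0.219),
            ("im_ifnb1a", "p_spms_mod_to_sev", 0.3),
            ("sc_ifnb1a", "p_rrms_mod_to_spms_mod", 0.197),
            ("sc_ifnb1b", "p_rrms_mod_to_sev", 0.15),
            ("sc_ifnb1b", "relapse_rate_rrms_cycle1", 1.68),
            ("natural_history", "relapse_rate_rrms_other", 2.04),
            ("sc_ifnb1a", "relapse_rate_spms", 0.5),
        ],
    )
    def test_transition_spot_values(self, params, cls, field, expected):
        assert getattr(params.transitions[cls], field) == expected

    @pytest.mark.parametrize(
        "cls,key,expected",
        [
            ("im_ifnb1a", ("rrms_mod", "cycle_2"), 0.26),
            ("sc_ifnb1a", ("rrms_mod", "cycle_2"), 0.42),
            ("sc_ifnb1b", ("rrms_mod", "cycle_2"), 0.247),
            ("im_ifnb1a", ("rrms_mild", "cycles_1_2"), 0.04),
            ("sc_ifnb1b", ("spms_mod", "all"), 0.25),
        ],
    )
    def test_withdrawal_spot_values(self, params, cls, key, expected):
        assert params.transitions[cls].withdrawal[key] == expected

    def test_transition_table_maps_bijectively_onto_fields(self, params):
        """Every cell of the transition/withdrawal table is consumed by
        exactly one field of exactly one efficacy-class block."""
        import pandas as pd
        from importlib import resources

        csv = resources.files("mscea").joinpath("data/table5_transitions.csv")
        with resources.as_file(csv) as f:
            df = pd.read_csv(f).set_index("parameter")
        wd_rows = {
            "wd_rrms_mild_cycles_1_2": ("rrms_mild", "cycles_1_2"),
            "wd_rrms_mild_other": ("rrms_mild", "other"),
            "wd_rrms_mod_cycle_2": ("rrms_mod", "cycle_2"),
            "wd_rrms_mod_other": ("rrms_mod", "other"),
            "wd_spms_mod_all": ("spms_mod", "all"),
        }
        n_cells = 0
        for cls in df.columns:
            tp = params.transitions[cls]
            consumed = 0
            for row, value in df[cls].items():
                if pd.isna(value):
                    continue
                n_cells += 1
                if row in wd_rows:
                    assert tp.withdrawal[wd_rows[row]] == float(value)
                else:
                    assert getattr(tp, row) == float(value)
                consumed += 1
            n_fields = len(TransitionParams._PROGRESSION_FIELDS) + len(
                TransitionParams._RELAPSE_FIELDS
            ) + len(tp.withdrawal)
            assert consumed == n_fields
        # 4 classes x 8 clinical rows + 3 treated classes x 5 withdrawal rows
        assert n_cells == 4 * 8 + 3 * 5

    def test_mortality_table_values_and_extrapolation(self, params):
        assert params.mortality.death_prob(30) == pytest.approx(0.0769)
        assert params.mortality.death_prob(36) == pytest.approx(0.0761)
        assert params.mortality.death_prob(58) == pytest.approx(0.1419)
        # beyond the last band the 66-70 value is carried forward
        assert params.mortality.death_prob(85) == pytest.approx(0.189)

    def test_mortality_band_hazard_interpretation_is_milder(self, params):
        per_cycle = params.mortality.death_prob(30, "per_cycle")
        band = params.mortality.death_prob(30, "band_hazard", 2.0)
        # a 6-year band probability spread over a 2-year cycle is smaller
        assert band < per_cycle
        assert band == pytest.approx(1 - (1 - 0.0769) ** (2 / 6))

    @pytest.mark.parametrize(
        "instrument,state,expected",
        [
            ("literature", "rrms_mild", 0.68),
            ("literature", "rrms_sev", 0.17),
            ("vas", "spms_mod", 0.58),
            ("eq5d", "spms_sev", 0.02),
            ("hui3", "rrms_mod", 0.41),
        ],
    )
    def test_utility_spot_values(self, params, instrument, state, expected):
        assert params.utilities[instrument].utilities[state] == expected

    def test_relapse_utility_losses(self, params):
        assert params.utilities["literature"].relapse_utility_loss == 0.5
        for inst in ("vas", "eq5d", "hui3"):
            assert params.utilities[inst].relapse_utility_loss == 0.42

    def test_cost_block_items_sum_to_printed_totals(self, params):
        c = params.costs
        # e.g. other direct medical in the severe band: 14+326+816+387 = 1543
        assert sum(c.other_direct_medical["rrms_sev"].values()) == 1543
        assert c.other_direct_medical_total["rrms_sev"] == 1543
        for block in ("other_direct_medical", "non_medical_direct", "indirect"):
            items = getattr(c, block)
            totals = getattr(c, f"{block}_total")
            for state in items:
                assert sum(items[state].values()) == pytest.approx(
                    totals[state], abs=1.0
                )

    def test_drug_costs_zero_in_severe_states(self, params):
        for pid, per_state in params.costs.drug.items():
            assert per_state["rrms_sev"] == 0.0
            assert per_state["spms_sev"] == 0.0
            assert per_state["rrms_mild"] > 0.0

    def test_relapse_costs_by_ms_type(self, params):
        assert params.costs.relapse_cost == {"rrms": 33.0, "spms": 54.0}

    def test_config_defaults(self, params):
        cfg = params.config
        assert cfg.n_cycles == 15
        assert cfg.cycle_length_years == 2
        assert cfg.discount_rate_cost == 0.072
        assert cfg.discount_rate_qaly == 0.03
        assert cfg.gdp_per_capita == 5810

    def test_products_share_clinical_parameters_within_class(self, params):
        brand = params.product("rebif")
        cbp = params.product("cbp_sc_1a")
        assert brand.efficacy_class == cbp.efficacy_class
        assert cbp.annual_drug_cost < brand.annual_drug_cost


class TestValidation:
    def test_out_of_range_probability_rejected(self, fresh_params):
        fresh_params.transitions["im_ifnb1a"].p_rrms_mild_to_mod = 1.2
        with pytest.raises(ValidationError, match="p_rrms_mild_to_mod"):
            fresh_params.validate()

    def test_natural_history_with_withdrawal_rejected(self, fresh_params):
        fresh_params.natural_history.withdrawal[("rrms_mild", "other")] = 0.1
        with pytest.raises(ValidationError, match="natural-history"):
            fresh_params.validate()

    def test_missing_withdrawal_entry_rejected(self, fresh_params):
        del fresh_params.transitions["im_ifnb1a"].withdrawal[("spms_mod", "all")]
        with pytest.raises(ValidationError, match="missing withdrawal"):
            fresh_params.validate()

    def test_cost_total_mismatch_rejected(self, fresh_params):
        fresh_params.costs.indirect["rrms_mild"]["absence_from_work"] += 5.0
        with pytest.raises(ValidationError, match="indirect"):
            fresh_params.validate()

    def test_cross_price_class_switch_target_rejected(self, params):
        policy = SwitchingPolicy(
            split={
                p.id: (("cbp_im_1a",), (0.5,), 0.5) if p.id == "avonex"
                else ((), (), 1.0)
                for p in params.products
            }
        )
        with pytest.raises(ValidationError, match="price class"):
            policy.validate(params.products)

    def test_switch_probabilities_must_sum_to_one(self, params):
        policy = SwitchingPolicy(
            split={
                p.id: (("rebif",), (0.5,), 0.6) if p.id == "avonex"
                else ((), (), 1.0)
                for p in params.products
            }
        )
        with pytest.raises(ValidationError, match="sum"):
            policy.validate(params.products)

    def test_horizon_must_span_thirty_years(self):
        with pytest.raises(ValidationError, match="30-year"):
            ModelConfig(n_cycles=10).validate()

    def test_noncontiguous_mortality_bands_rejected(self):
        with pytest.raises(ValidationError, match="contiguous"):
            MortalityTable(bands=[(30, 35, 0.07), (40, 45, 0.08)]).validate()

    def test_rrms_utility_monotonicity_enforced(self):
        us = UtilitySet(
            instrument="vas",
            utilities={
                "rrms_mild": 0.5,
                "rrms_mod": 0.7,
                "rrms_sev": 0.2,
                "spms_mod": 0.5,
                "spms_sev": 0.2,
            },
            relapse_utility_loss=0.4,
        )
        with pytest.raises(ValidationError, match="non-increasing"):
            us.validate()

    def test_missing_file_is_a_format_error(self, tmp_path):
        with pytest.raises(ParameterFormatError, match="not found"):
            load_parameters(tmp_path / "nope.yaml")


class TestRoundTrip:
    def test_save_then_load_is_identity(self, params, tmp_path):
        path = save_parameters(params, tmp_path / "bundle.yaml")
        reloaded = load_parameters(path)
        assert reloaded.to_dict() == params.to_dict()
        assert reloaded.fingerprint() == params.fingerprint()

    def test_fingerprint_changes_with_parameters(self, fresh_params, params):
        fresh_params.config.discount_rate_cost = 0.05
        assert fresh_params.fingerprint() != params.fingerprint()


class TestWeightedDrugCost:
    def test_single_component(self):
        assert weighted_drug_cost([(100.0, 1.0)]) == 100.0

    def test_symmetric_mean(self):
        assert weighted_drug_cost([(100.0, 0.5), (200.0, 0.5)]) == 150.0

    def test_market_share_aggregate_matches_printed_row(self):
        # two-component row at 98% / 2% shares reproducing the bundled 3762
        assert weighted_drug_cost([(3700.0, 0.98), (6800.0, 0.02)]) == pytest.approx(
            3762.0
        )

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            weighted_drug_cost([(100.0, 0.6), (200.0, 0.5)])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e5, allow_nan=False),
                st.floats(0.01, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_weighted_mean_bounded_and_permutation_invariant(self, components):
        total = sum(s for _, s in components)
        components = [(c, s / total) for c, s in components]
        value = weighted_drug_cost(components)
        costs = [c for c, _ in components]
        assert min(costs) - 1e-6 <= value <= max(costs) + 1e-6
        assert math.isclose(
            value, weighted_drug_cost(list(reversed(components))), rel_tol=1e-12
        )
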