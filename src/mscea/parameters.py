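"""Typed, validated model inputs and their file representation.

Every input of the cost-utility model lives here: per-cycle transition and
withdrawal probabilities by efficacy class, the age-banded mortality table,
utility weights by elicitation instrument, the annual cost blocks by health
state, the product catalogue with price classes, the switching policy, and
the run configuration (cycle structure, discount rates, WHO threshold
inputs).

Parameter files are a YAML master referencing one CSV per input table; the
bundled ``paper_2012.yaml`` fixture carries the default parameterisation
(2012 USD, Iranian societal perspective).  ``load_parameters`` /
``save_parameters`` round-trip the full bundle.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .states import HealthState, LIVING_STATES

__all__ = [
    "ValidationError",
    "ParameterFormatError",
    "EFFICACY_CLASSES",
    "NATURAL_HISTORY",
    "TransitionParams",
    "MortalityTable",
    "UtilitySet",
    "CostSet",
    "ProductSpec",
    "SwitchingPolicy",
    "ModelConfig",
    "ParameterSet",
    "weighted_drug_cost",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]


class ValidationError(ValueError):
    """A parameter value violates a documented invariant."""


class ParameterFormatError(ValueError):
    """A parameter file is missing a block or cannot be parsed."""


NATURAL_HISTORY = "natural_history"
#: Efficacy classes: untreated natural history plus the three interferon-beta
#: preparations (intramuscular IFNb-1a, subcutaneous IFNb-1a, subcutaneous
#: IFNb-1b).  Brand and copied/biosimilar products share the class of their
#: reference preparation.
EFFICACY_CLASSES = (NATURAL_HISTORY, "im_ifnb1a", "sc_ifnb1a", "sc_ifnb1b")

INSTRUMENTS = ("literature", "vas", "eq5d", "hui3")

_STATE_KEYS = tuple(s.value for s in LIVING_STATES)

#: (band, cycle-band) keys of the withdrawal table.
WITHDRAWAL_KEYS = (
    ("rrms_mild", "cycles_1_2"),
    ("rrms_mild", "other"),
    ("rrms_mod", "cycle_2"),
    ("rrms_mod", "other"),
    ("spms_mod", "all"),
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} = {value!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# transition / withdrawal probabilities (one block per efficacy class)


@dataclass
class TransitionParams:
    """Per-cycle disease progression, relapse and withdrawal inputs.

    All probabilities refer to one 2-year model cycle.  The RRMS-to-SPMS
    entries apply from cycle 3 onwards only (conversion is assumed not to
    occur within roughly the first five years after diagnosis); the gate is
    applied by the transition-matrix builder, not stored here.  Relapse rates
    are expected relapse counts per cycle.  ``withdrawal`` maps the
    (state band, cycle band) keys of the source table to probabilities; the
    natural-history class has no withdrawal entries.
    """

    efficacy_class: str
    p_rrms_mild_to_mod: float
    p_rrms_mod_to_sev: float
    p_rrms_mod_to_spms_mod: float
    p_rrms_sev_to_spms_sev: float
    p_spms_mod_to_sev: float
    relapse_rate_rrms_cycle1: float
    relapse_rate_rrms_other: float
    relapse_rate_spms: float
    withdrawal: dict[tuple[str, str], float] = field(default_factory=dict)

    _PROGRESSION_FIELDS = (
        "p_rrms_mild_to_mod",
        "p_rrms_mod_to_sev",
        "p_rrms_mod_to_spms_mod",
        "p_rrms_sev_to_spms_sev",
        "p_spms_mod_to_sev",
    )
    _RELAPSE_FIELDS = (
        "relapse_rate_rrms_cycle1",
        "relapse_rate_rrms_other",
        "relapse_rate_spms",
    )

    def validate(self) -> None:
        if self.efficacy_class not in EFFICACY_CLASSES:
            raise ValidationError(
                f"unknown efficacy class {self.efficacy_class!r}"
            )
        for name in self._PROGRESSION_FIELDS:
            _check_prob(f"{self.efficacy_class}.{name}", getattr(self, name))
        for name in self._RELAPSE_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.efficacy_class}.{name} must be >= 0"
                )
        if self.efficacy_class == NATURAL_HISTORY:
            if self.withdrawal:
                raise ValidationError(
                    "natural-history class must have no withdrawal entries"
                )
            return
        for key in WITHDRAWAL_KEYS:
            if key not in self.withdrawal:
                raise ValidationError(
                    f"{self.efficacy_class}: missing withdrawal entry {key}"
                )
            _check_prob(f"{self.efficacy_class}.withdrawal{key}", self.withdrawal[key])
        extra = set(self.withdrawal) - set(WITHDRAWAL_KEYS)
        if extra:
            raise ValidationError(
                f"{self.efficacy_class}: unknown withdrawal keys {sorted(extra)}"
            )

    def withdrawal_prob(self, health: HealthState, cycle: int) -> float:
        """Probability of leaving the current product during ``cycle``.

        Zero for the natural-history class and for non-eligible states.
        """
        if not self.withdrawal or not health.ifn_eligible:
            return 0.0
        if health is HealthState.RRMS_MILD:
            key = ("rrms_mild", "cycles_1_2" if cycle <= 2 else "other")
        elif health is HealthState.RRMS_MOD:
            key = ("rrms_mod", "cycle_2" if cycle == 2 else "other")
        else:  # SPMS_MOD
            key = ("spms_mod", "all")
        return self.withdrawal[key]

    def relapse_rate(self, health: HealthState, cycle: int) -> float:
        """Expected relapses per cycle for an occupant of ``health``."""
        ms = health.ms_type
        if ms == "rrms":
            return (
                self.relapse_rate_rrms_cycle1
                if cycle == 1
                else self.relapse_rate_rrms_other
            )
        if ms == "spms":
            return self.relapse_rate_spms
        return 0.0


# ---------------------------------------------------------------------------
# mortality


@dataclass
class MortalityTable:
    """Age-banded death probabilities for MS patients.

    ``bands`` is an ordered list of ``(age_lo, age_hi, probability)`` with
    contiguous, non-overlapping bands.  (The source figures are not strictly
    monotone in age — the second band dips slightly below the first — so no
    monotonicity is enforced.)  The default interpretation reads each figure as the death
    probability per 2-year model cycle for a patient whose current age falls
    in the band; the alternative ``band_hazard`` interpretation reads it as
    the probability of dying over the whole band width under a constant
    hazard, converted to the cycle length.  Ages beyond the last band reuse
    the last band's value.
    """

    bands: list[tuple[int, int, float]]

    def validate(self) -> None:
        if not self.bands:
            raise ValidationError("mortality table is empty")
        prev_hi = None
        for lo, hi, p in self.bands:
            if hi < lo:
                raise ValidationError(f"mortality band {lo}-{hi} is inverted")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ValidationError(
                    f"mortality bands not contiguous at {lo}-{hi}"
                )
            _check_prob(f"mortality[{lo}-{hi}]", p)
            prev_hi = hi

    def _band(self, age: float) -> tuple[int, int, float]:
        a = math.floor(age)
        if a < self.bands[0][0]:
            return self.bands[0]
        for lo, hi, p in self.bands:
            if lo <= a <= hi:
                return (lo, hi, p)
        return self.bands[-1]

    def death_prob(
        self,
        age: float,
        interpretation: str = "per_cycle",
        cycle_length_years: float = 2.0,
    ) -> float:
        lo, hi, p = self._band(age)
        if interpretation == "per_cycle":
            return p
        if interpretation == "band_hazard":
            width = hi - lo + 1
            return 1.0 - (1.0 - p) ** (cycle_length_years / width)
        raise ValidationError(
            f"unknown mortality interpretation {interpretation!r}"
        )


# ---------------------------------------------------------------------------
# utilities


@dataclass
class UtilitySet:
    """Utility weights for one elicitation instrument.

    ``utilities`` maps the five living states to weights in [0, 1]; Death is
    fixed at 0.  ``relapse_utility_loss`` is the utility decrement while a
    relapse episode lasts (the episode duration is a run-configuration
    parameter, not part of the instrument).
    """

    instrument: str
    utilities: dict[str, float]
    relapse_utility_loss: float

    def validate(self) -> None:
        missing = set(_STATE_KEYS) - set(self.utilities)
        if missing:
            raise ValidationError(
                f"utility set {self.instrument!r} missing states {sorted(missing)}"
            )
        for k, v in self.utilities.items():
            _check_prob(f"utility[{self.instrument}][{k}]", v)
        _check_prob(f"relapse_utility_loss[{self.instrument}]", self.relapse_utility_loss)
        u = self.utilities
        if not (u["rrms_mild"] >= u["rrms_mod"] >= u["rrms_sev"]):
            raise ValidationError(
                f"utility set {self.instrument!r}: RRMS utilities must be "
                "non-increasing in disability"
            )

    def state_utility(self, health: HealthState) -> float:
        if health is HealthState.DEATH:
            return 0.0
        return self.utilities[health.value]


# ---------------------------------------------------------------------------
# costs


_COST_BLOCKS = ("other_direct_medical", "non_medical_direct", "indirect")


@dataclass
class CostSet:
    """Annual per-patient costs by health state (2012 USD).

    Structure mirrors the source cost table: interferon drug costs per
    product, symptomatic co-medication rows (antidepressants with their
    first-three-cycles vs later split, anti-spasm, anti-fatigue, painkiller),
    NSAID side-effect prophylaxis per interferon preparation, and the three
    itemised blocks (other direct medical, non-medical direct, indirect) with
    printed block totals kept for cross-checking.  Relapse costs are per
    episode by MS type.
    """

    drug: dict[str, dict[str, float]]                 # product id -> state -> $
    antidepressant_first3: dict[str, float]
    antidepressant_other: dict[str, float]
    anti_spasm: dict[str, float]
    anti_fatigue: dict[str, float]
    painkiller: dict[str, float]
    nsaid: dict[str, dict[str, float]]                # efficacy class -> state -> $
    other_direct_medical: dict[str, dict[str, float]] # state -> item -> $
    other_direct_medical_total: dict[str, float]
    non_medical_direct: dict[str, dict[str, float]]
    non_medical_direct_total: dict[str, float]
    indirect: dict[str, dict[str, float]]
    indirect_total: dict[str, float]
    relapse_items: dict[str, dict[str, float]]        # state -> item -> $
    relapse_cost: dict[str, float]                    # ms type -> $ per relapse

    def validate(self) -> None:
        def _nonneg(name: str, mapping: dict[str, float]) -> None:
            for k, v in mapping.items():
                if v < 0:
                    raise ValidationError(f"{name}[{k}] = {v} is negative")

        for pid, per_state in self.drug.items():
            _nonneg(f"drug[{pid}]", per_state)
            for sev in ("rrms_sev", "spms_sev"):
                if per_state.get(sev, 0.0) != 0.0:
                    raise ValidationError(
                        f"drug[{pid}][{sev}] must be 0 (not interferon-eligible)"
                    )
        for name in (
            "antidepressant_first3",
            "antidepressant_other",
            "anti_spasm",
            "anti_fatigue",
            "painkiller",
        ):
            _nonneg(name, getattr(self, name))
        for cls, per_state in self.nsaid.items():
            _nonneg(f"nsaid[{cls}]", per_state)
            for sev in ("rrms_sev", "spms_sev"):
                if per_state.get(sev, 0.0) != 0.0:
                    raise ValidationError(
                        f"nsaid[{cls}][{sev}] must be 0 (no interferon in EDSS > 6)"
                    )
        for block in _COST_BLOCKS:
            items = getattr(self, block)
            totals = getattr(self, f"{block}_total")
            for state in _STATE_KEYS:
                _nonneg(f"{block}[{state}]", items[state])
                s = sum(items[state].values())
                if abs(s - totals[state]) > 1.0:  # printed totals, +-1 USD rounding
                    raise ValidationError(
                        f"{block}[{state}] items sum to {s}, printed total "
                        f"{totals[state]}"
                    )
        _nonneg("relapse_cost", self.relapse_cost)
        for ms in ("rrms", "spms"):
            if ms not in self.relapse_cost:
                raise ValidationError(f"relapse_cost missing MS type {ms!r}")

    def symptomatic_cost(self, state_key: str, cycle: int) -> float:
        """Annual symptomatic co-medication cost (excluding NSAID)."""
        anti_dep = (
            self.antidepressant_first3[state_key]
            if cycle <= 3
            else self.antidepressant_other[state_key]
        )
        return (
            anti_dep
            + self.anti_spasm[state_key]
            + self.anti_fatigue[state_key]
            + self.painkiller[state_key]
        )


def weighted_drug_cost(components: list[tuple[float, float]]) -> float:
    """Market-share-weighted annual drug cost.

    ``components`` is a list of ``(annual_cost_usd, market_share)`` pairs;
    shares must be non-negative and sum to 1 (tolerance 1e-9).
    """
    if not components:
        raise ValidationError("weighted_drug_cost requires at least one component")
    total_share = 0.0
    for cost, share in components:
        if share < 0:
            raise ValidationError(f"negative market share {share}")
        if cost < 0:
            raise ValidationError(f"negative component cost {cost}")
        total_share += share
    if abs(total_share - 1.0) > 1e-9:
        raise ValidationError(
            f"market shares sum to {total_share!r}, expected 1"
        )
    return sum(cost * share for cost, share in components)


# ---------------------------------------------------------------------------
# products / switching


@dataclass
class ProductSpec:
    """One treatment strategy: a marketed interferon-beta product (or group).

    Two products sharing an ``efficacy_class`` share all clinical parameters
    (transition, relapse and withdrawal probabilities); the ``price_class``
    (brand vs copied biopharmaceutical/biosimilar) separates the drug price
    and constrains permitted switch targets.  ``components`` optionally lists
    ``(annual_cost, market_share)`` pairs for rows aggregating several items;
    when present, the annual drug cost is their share-weighted mean.
    """

    id: str
    label: str
    efficacy_class: str
    price_class: str
    annual_drug_cost: float
    components: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.components is not None:
            self.annual_drug_cost = weighted_drug_cost(self.components)

    def validate(self) -> None:
        if self.efficacy_class not in EFFICACY_CLASSES[1:]:
            raise ValidationError(
                f"product {self.id!r}: efficacy class must be one of "
                f"{EFFICACY_CLASSES[1:]}, got {self.efficacy_class!r}"
            )
        if self.price_class not in ("brand", "cbp"):
            raise ValidationError(
                f"product {self.id!r}: price class must be 'brand' or 'cbp'"
            )
        if self.annual_drug_cost < 0:
            raise ValidationError(f"product {self.id!r}: negative drug cost")


@dataclass
class SwitchingPolicy:
    """Once-only switch rules applied when a patient withdraws.

    Within the first ``switch_window_cycles`` cycles a withdrawing patient
    who has never switched moves to one of the permitted same-price-class
    alternative products or off treatment, according to ``split``:
    ``split[product_id]`` is ``(targets, probs, p_off)`` where ``probs`` and
    ``p_off`` sum to 1 and are conditional on withdrawing.  From cycle
    ``switch_window_cycles + 1`` on, and for patients who already switched,
    all withdrawal mass goes off treatment.  Off-treatment is absorbing:
    reinitiation is never permitted.
    """

    split: dict[str, tuple[tuple[str, ...], tuple[float, ...], float]]
    switch_window_cycles: int = 3
    max_switches: int = 1

    @classmethod
    def uniform(cls, products: list[ProductSpec], switch_window_cycles: int = 3) -> "SwitchingPolicy":
        """Uniform split over the permitted alternatives and off-treatment."""
        split = {}
        for p in products:
            targets = tuple(
                q.id for q in products
                if q.id != p.id and q.price_class == p.price_class
            )
            n = len(targets) + 1
            probs = tuple(1.0 / n for _ in targets)
            split[p.id] = (targets, probs, 1.0 - sum(probs))
        return cls(split=split, switch_window_cycles=switch_window_cycles)

    @classmethod
    def with_switch_prob(
        cls,
        products: list[ProductSpec],
        switch_prob: float,
        switch_window_cycles: int = 3,
    ) -> "SwitchingPolicy":
        """Total switch probability ``switch_prob`` split equally over targets."""
        if not (0.0 <= switch_prob <= 1.0):
            raise ValidationError(f"switch probability {switch_prob} outside [0, 1]")
        split = {}
        for p in products:
            targets = tuple(
                q.id for q in products
                if q.id != p.id and q.price_class == p.price_class
            )
            if targets:
                probs = tuple(switch_prob / len(targets) for _ in targets)
                split[p.id] = (targets, probs, 1.0 - switch_prob)
            else:
                split[p.id] = ((), (), 1.0)
        return cls(split=split, switch_window_cycles=switch_window_cycles)

    def validate(self, products: list[ProductSpec]) -> None:
        if self.max_switches != 1:
            raise ValidationError("only max_switches = 1 is supported")
        if self.switch_window_cycles < 0:
            raise ValidationError("switch window must be >= 0 cycles")
        by_id = {p.id: p for p in products}
        for pid, (targets, probs, p_off) in self.split.items():
            if pid not in by_id:
                raise ValidationError(f"switching policy references unknown product {pid!r}")
            if len(targets) != len(probs):
                raise ValidationError(f"switching policy for {pid!r}: targets/probs mismatch")
            for t in targets:
                if t == pid:
                    raise ValidationError(f"switching policy for {pid!r}: self-switch")
                if t not in by_id:
                    raise ValidationError(
                        f"switching policy for {pid!r}: unknown target {t!r}"
                    )
                if by_id[t].price_class != by_id[pid].price_class:
                    raise ValidationError(
                        f"switching policy for {pid!r}: target {t!r} crosses "
                        "price classes (switching is permitted within brands "
                        "or within CBPs/biosimilars only)"
                    )
            total = sum(probs) + p_off
            if any(p < 0 for p in probs) or p_off < 0 or abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"switching policy for {pid!r}: probabilities sum to {total!r}"
                )
        for p in products:
            if p.id not in self.split:
                raise ValidationError(f"switching policy missing product {p.id!r}")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class ModelConfig:
    """Cycle structure, discounting and analysis-level constants.

    The horizon is 15 two-year cycles (30 years) for a cohort entering at age
    30.  Costs discount at 7.2%/year and QALYs at 3%/year; with the default
    ``first_year_end`` convention, cycle ``t`` flows are discounted to the end
    of the cycle's first year, i.e. by ``(1+r)^-(2t-1)``.  The relapse
    episode duration converts the per-relapse utility decrement into QALYs
    lost per relapse.
    """

    n_cycles: int = 15
    cycle_length_years: float = 2.0
    start_age: float = 30.0
    discount_rate_cost: float = 0.072
    discount_rate_qaly: float = 0.03
    discount_convention: str = "first_year_end"
    relapse_episode_duration_years: float = 0.25
    gdp_per_capita: float = 5810.0
    currency: str = "USD-2012"
    irr_per_usd: float = 12260.0
    mortality_interpretation: str = "per_cycle"
    half_cycle_correction: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        for name in ("discount_rate_cost", "discount_rate_qaly"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be > 0")
        if abs(self.n_cycles * self.cycle_length_years - 30.0) > 1e-9:
            raise ValidationError(
                "cycle structure must span the 30-year horizon "
                f"(got {self.n_cycles} x {self.cycle_length_years} years)"
            )
        if self.relapse_episode_duration_years < 0:
            raise ValidationError("relapse episode duration must be >= 0")
        if self.gdp_per_capita <= 0:
            raise ValidationError("gdp_per_capita must be > 0")
        if self.discount_convention not in ("first_year_end", "cycle_end"):
            raise ValidationError(
                f"unknown discount convention {self.discount_convention!r}"
            )
        if self.mortality_interpretation not in ("per_cycle", "band_hazard"):
            raise ValidationError(
                f"unknown mortality interpretation {self.mortality_interpretation!r}"
            )

    def age_at_cycle_start(self, cycle: int) -> float:
        return self.start_age + (cycle - 1) * self.cycle_length_years


# ---------------------------------------------------------------------------
# the full bundle


@dataclass
class ParameterSet:
    """All inputs for one model run: the validated bundle of every block."""

    transitions: dict[str, TransitionParams]
    mortality: MortalityTable
    utilities: dict[str, UtilitySet]
    costs: CostSet
    products: list[ProductSpec]
    switching: SwitchingPolicy
    config: ModelConfig

    def validate(self) -> "ParameterSet":
        if NATURAL_HISTORY not in self.transitions:
            raise ValidationError("missing natural-history transition block")
        for cls, tp in self.transitions.items():
            if tp.efficacy_class != cls:
                raise ValidationError(
                    f"transition block keyed {cls!r} labelled {tp.efficacy_class!r}"
                )
            tp.validate()
        self.mortality.validate()
        for inst, us in self.utilities.items():
            if us.instrument != inst:
                raise ValidationError(
                    f"utility set keyed {inst!r} labelled {us.instrument!r}"
                )
            us.validate()
        self.costs.validate()
        ids = [p.id for p in self.products]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate product ids")
        for p in self.products:
            p.validate()
            if p.efficacy_class not in self.transitions:
                raise ValidationError(
                    f"product {p.id!r}: no transition block for class "
                    f"{p.efficacy_class!r}"
                )
            if p.id not in self.costs.drug:
                raise ValidationError(f"product {p.id!r}: no drug cost row")
        self.switching.validate(self.products)
        self.config.validate()
        return self

    # -- lookups ------------------------------------------------------------

    def product(self, product_id: str) -> ProductSpec:
        for p in self.products:
            if p.id == product_id:
                return p
        raise KeyError(f"unknown product {product_id!r}")

    def transition(self, efficacy_class: str) -> TransitionParams:
        return self.transitions[efficacy_class]

    @property
    def natural_history(self) -> TransitionParams:
        return self.transitions[NATURAL_HISTORY]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- provenance ---------------------------------------------------------

    def to_dict(self) -> dict:
        """Plain-data representation (used for saving and fingerprinting)."""
        return {
            "config": {**self.config.__dict__},
            "products": [
                {
                    "id": p.id,
                    "label": p.label,
                    "efficacy_class": p.efficacy_class,
                    "price_class": p.price_class,
                    "annual_drug_cost": p.annual_drug_cost,
                    "components": (
                        [list(c) for c in p.components] if p.components else None
                    ),
                }
                for p in self.products
            ],
            "switching": {
                "switch_window_cycles": self.switching.switch_window_cycles,
                "max_switches": self.switching.max_switches,
                "split": {
                    pid: {
                        "targets": list(targets),
                        "probs": list(probs),
                        "off": p_off,
                    }
                    for pid, (targets, probs, p_off) in sorted(
                        self.switching.split.items()
                    )
                },
            },
            "transitions": {
                cls: {
                    **{
                        f: getattr(tp, f)
                        for f in (
                            *TransitionParams._PROGRESSION_FIELDS,
                            *TransitionParams._RELAPSE_FIELDS,
                        )
                    },
                    "withdrawal": {
                        f"{band}:{cyc}": v
                        for (band, cyc), v in sorted(tp.withdrawal.items())
                    },
                }
                for cls, tp in sorted(self.transitions.items())
            },
            "mortality": [list(b) for b in self.mortality.bands],
            "utilities": {
                inst: {
                    "utilities": dict(sorted(us.utilities.items())),
                    "relapse_utility_loss": us.relapse_utility_loss,
                }
                for inst, us in sorted(self.utilities.items())
            },
            "costs": {
                "drug": {k: dict(sorted(v.items())) for k, v in sorted(self.costs.drug.items())},
                "antidepressant_first3": dict(sorted(self.costs.antidepressant_first3.items())),
                "antidepressant_other": dict(sorted(self.costs.antidepressant_other.items())),
                "anti_spasm": dict(sorted(self.costs.anti_spasm.items())),
                "anti_fatigue": dict(sorted(self.costs.anti_fatigue.items())),
                "painkiller": dict(sorted(self.costs.painkiller.items())),
                "nsaid": {k: dict(sorted(v.items())) for k, v in sorted(self.costs.nsaid.items())},
                **{
                    block: {
                        s: dict(sorted(items.items()))
                        for s, items in sorted(getattr(self.costs, block).items())
                    }
                    for block in _COST_BLOCKS
                },
                **{
                    f"{block}_total": dict(sorted(getattr(self.costs, f"{block}_total").items()))
                    for block in _COST_BLOCKS
                },
                "relapse_items": {
                    s: dict(sorted(v.items()))
                    for s, v in sorted(self.costs.relapse_items.items())
                },
                "relapse_cost": dict(sorted(self.costs.relapse_cost.items())),
            },
        }

    def fingerprint(self) -> str:
        """SHA-256 over the canonical plain-data representation."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# file I/O


def _read_csv(path: Path, block: str) -> pd.DataFrame:
    if not path.exists():
        raise ParameterFormatError(f"{block}: table file {path} not found")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - exercised via bad fixtures
        raise ParameterFormatError(f"{block}: cannot parse {path}: {exc}") from exc


def _parse_transitions(df: pd.DataFrame) -> dict[str, TransitionParams]:
    classes = [c for c in df.columns if c != "parameter"]
    rows = df.set_index("parameter")
    out: dict[str, TransitionParams] = {}
    wd_map = {
        "wd_rrms_mild_cycles_1_2": ("rrms_mild", "cycles_1_2"),
        "wd_rrms_mild_other": ("rrms_mild", "other"),
        "wd_rrms_mod_cycle_2": ("rrms_mod", "cycle_2"),
        "wd_rrms_mod_other": ("rrms_mod", "other"),
        "wd_spms_mod_all": ("spms_mod", "all"),
    }
    for cls in classes:
        try:
            kwargs = {
                f: float(rows.at[f, cls])
                for f in (
                    *TransitionParams._PROGRESSION_FIELDS,
                    *TransitionParams._RELAPSE_FIELDS,
                )
            }
        except KeyError as exc:
            raise ParameterFormatError(
                f"transitions: missing row {exc.args[0]!r}"
            ) from exc
        withdrawal = {}
        for row_name, key in wd_map.items():
            if row_name in rows.index:
                v = rows.at[row_name, cls]
                if pd.notna(v):
                    withdrawal[key] = float(v)
        out[cls] = TransitionParams(
            efficacy_class=cls, withdrawal=withdrawal, **kwargs
        )
    return out


def _parse_costs(df: pd.DataFrame) -> CostSet:
    def rows(cat: str) -> pd.DataFrame:
        return df[df["category"] == cat].set_index("item")

    def per_state(row: pd.Series) -> dict[str, float]:
        return {s: float(row[s]) for s in _STATE_KEYS}

    try:
        drug = {pid: per_state(r) for pid, r in rows("drug").iterrows()}
        sym = rows("symptomatic")
        nsaid = {cls: per_state(r) for cls, r in rows("nsaid").iterrows()}
        blocks = {}
        totals = {}
        for block in _COST_BLOCKS:
            b = rows(block)
            blocks[block] = {
                s: {item: float(b.at[item, s]) for item in b.index if item != "total"}
                for s in _STATE_KEYS
            }
            totals[block] = {s: float(b.at["total", s]) for s in _STATE_KEYS}
        rel = rows("relapse")
        relapse_items = {
            s: {item: float(rel.at[item, s]) for item in rel.index if item != "total"}
            for s in _STATE_KEYS
        }
        relapse_cost = {
            "rrms": float(rel.at["total", "rrms_mild"]),
            "spms": float(rel.at["total", "spms_mod"]),
        }
        return CostSet(
            drug=drug,
            antidepressant_first3=per_state(sym.loc["antidepressant_first3"]),
            antidepressant_other=per_state(sym.loc["antidepressant_other"]),
            anti_spasm=per_state(sym.loc["anti_spasm"]),
            anti_fatigue=per_state(sym.loc["anti_fatigue"]),
            painkiller=per_state(sym.loc["painkiller"]),
            nsaid=nsaid,
            other_direct_medical=blocks["other_direct_medical"],
            other_direct_medical_total=totals["other_direct_medical"],
            non_medical_direct=blocks["non_medical_direct"],
            non_medical_direct_total=totals["non_medical_direct"],
            indirect=blocks["indirect"],
            indirect_total=totals["indirect"],
            relapse_items=relapse_items,
            relapse_cost=relapse_cost,
        )
    except KeyError as exc:
        raise ParameterFormatError(f"costs: missing row/column {exc.args[0]!r}") from exc


def _parse_switching(
    block: dict, products: list[ProductSpec]
) -> SwitchingPolicy:
    window = int(block.get("switch_window_cycles", 3))
    split_spec = block.get("split", "uniform")
    if split_spec == "uniform":
        policy = SwitchingPolicy.uniform(products, window)
    elif isinstance(split_spec, dict):
        split = {}
        for pid, entry in split_spec.items():
            split[pid] = (
                tuple(entry["targets"]),
                tuple(float(x) for x in entry["probs"]),
                float(entry["off"]),
            )
        policy = SwitchingPolicy(split=split, switch_window_cycles=window)
    else:
        raise ParameterFormatError(
            f"switching: split must be 'uniform' or a mapping, got {split_spec!r}"
        )
    policy.max_switches = int(block.get("max_switches", 1))
    return policy


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter bundle from a YAML master file.

    The YAML file names one CSV per input table (resolved relative to the
    YAML file's directory) and carries the configuration, product catalogue
    and switching-policy blocks inline.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterFormatError(f"parameter file {path} not found")
    try:
        master = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterFormatError(f"master file: cannot parse {path}: {exc}") from exc
    if not isinstance(master, dict):
        raise ParameterFormatError("master file: expected a mapping at top level")
    for block in ("tables", "config", "products", "switching"):
        if block not in master:
            raise ParameterFormatError(f"master file: missing block {block!r}")
    tables = master["tables"]
    base = path.parent
    for t in ("mortality", "transitions", "utilities", "costs"):
        if t not in tables:
            raise ParameterFormatError(f"tables: missing entry {t!r}")

    mort_df = _read_csv(base / tables["mortality"], "mortality")
    try:
        bands = [
            (int(r.age_lo), int(r.age_hi), float(r.mortality_rate_pct) / 100.0)
            for r in mort_df.itertuples()
        ]
    except AttributeError as exc:
        raise ParameterFormatError(f"mortality: missing column: {exc}") from exc
    mortality = MortalityTable(bands=bands)

    transitions = _parse_transitions(_read_csv(base / tables["transitions"], "transitions"))

    util_df = _read_csv(base / tables["utilities"], "utilities").set_index("state")
    utilities = {}
    for inst in INSTRUMENTS:
        if inst not in util_df.columns:
            raise ParameterFormatError(f"utilities: missing instrument column {inst!r}")
        utilities[inst] = UtilitySet(
            instrument=inst,
            utilities={s: float(util_df.at[s, inst]) for s in _STATE_KEYS},
            relapse_utility_loss=float(util_df.at["relapse_loss", inst]),
        )
        if float(util_df.at["death", inst]) != 0.0:
            raise ValidationError(f"utilities[{inst}]: death utility must be 0")

    costs = _parse_costs(_read_csv(base / tables["costs"], "costs"))

    products = []
    for entry in master["products"]:
        pid = entry["id"]
        components = entry.get("components")
        if components is not None:
            components = [(float(c), float(s)) for c, s in components]
            annual = 0.0  # recomputed from components in __post_init__
        else:
            if pid not in costs.drug:
                raise ParameterFormatError(f"products: no drug cost row for {pid!r}")
            annual = costs.drug[pid]["rrms_mild"]
        products.append(
            ProductSpec(
                id=pid,
                label=entry.get("label", pid),
                efficacy_class=entry["efficacy_class"],
                price_class=entry["price_class"],
                annual_drug_cost=annual,
                components=components,
            )
        )

    switching = _parse_switching(master["switching"], products)
    config = ModelConfig(**master["config"])

    return ParameterSet(
        transitions=transitions,
        mortality=mortality,
        utilities=utilities,
        costs=costs,
        products=products,
        switching=switching,
        config=config,
    ).validate()


def save_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Write a parameter bundle as YAML master + CSV tables.

    ``path`` is the master YAML file; the CSVs are written next to it with
    fixed names.  ``load_parameters(save_parameters(p, f))`` reproduces ``p``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent

    pd.DataFrame(
        [
            {"age_lo": lo, "age_hi": hi, "mortality_rate_pct": round(p * 100.0, 10)}
            for lo, hi, p in params.mortality.bands
        ]
    ).to_csv(base / "mortality.csv", index=False)

    wd_rows = {
        ("rrms_mild", "cycles_1_2"): "wd_rrms_mild_cycles_1_2",
        ("rrms_mild", "other"): "wd_rrms_mild_other",
        ("rrms_mod", "cycle_2"): "wd_rrms_mod_cycle_2",
        ("rrms_mod", "other"): "wd_rrms_mod_other",
        ("spms_mod", "all"): "wd_spms_mod_all",
    }
    trans_rows = []
    fields = (*TransitionParams._PROGRESSION_FIELDS, *TransitionParams._RELAPSE_FIELDS)
    classes = list(params.transitions)
    for f in fields:
        trans_rows.append(
            {"parameter": f, **{c: getattr(params.transitions[c], f) for c in classes}}
        )
    for key, row_name in wd_rows.items():
        trans_rows.append(
            {
                "parameter": row_name,
                **{
                    c: params.transitions[c].withdrawal.get(key)
                    for c in classes
                },
            }
        )
    pd.DataFrame(trans_rows).to_csv(base / "transitions.csv", index=False)

    util_rows = []
    for s in (*_STATE_KEYS, "relapse_loss", "death"):
        row = {"state": s}
        for inst, us in params.utilities.items():
            if s == "relapse_loss":
                row[inst] = us.relapse_utility_loss
            elif s == "death":
                row[inst] = 0.0
            else:
                row[inst] = us.utilities[s]
        util_rows.append(row)
    pd.DataFrame(util_rows).to_csv(base / "utilities.csv", index=False)

    cost_rows = []

    def add(cat: str, item: str, per_state: dict[str, float]) -> None:
        cost_rows.append(
            {"category": cat, "item": item, **{s: per_state[s] for s in _STATE_KEYS}}
        )

    c = params.costs
    for pid, per_state in c.drug.items():
        add("drug", pid, per_state)
    add("symptomatic", "antidepressant_first3", c.antidepressant_first3)
    add("symptomatic", "antidepressant_other", c.antidepressant_other)
    add("symptomatic", "anti_spasm", c.anti_spasm)
    add("symptomatic", "anti_fatigue", c.anti_fatigue)
    add("symptomatic", "painkiller", c.painkiller)
    for cls, per_state in c.nsaid.items():
        add("nsaid", cls, per_state)
    for block in _COST_BLOCKS:
        items = getattr(c, block)
        for item in items[_STATE_KEYS[0]]:
            add(block, item, {s: items[s][item] for s in _STATE_KEYS})
        add(block, "total", getattr(c, f"{block}_total"))
    for item in c.relapse_items[_STATE_KEYS[0]]:
        add("relapse", item, {s: c.relapse_items[s][item] for s in _STATE_KEYS})
    add(
        "relapse",
        "total",
        {
            s: c.relapse_cost["rrms" if s.startswith("rrms") else "spms"]
            for s in _STATE_KEYS
        },
    )
    pd.DataFrame(cost_rows).to_csv(base / "costs.csv", index=False)

    d = params.to_dict()
    master = {
        "tables": {
            "mortality": "mortality.csv",
            "transitions": "transitions.csv",
            "utilities": "utilities.csv",
            "costs": "costs.csv",
        },
        "config": d["config"],
        "products": [
            {k: v for k, v in p.items() if k != "annual_drug_cost" and v is not None}
            for p in d["products"]
        ],
        "switching": d["switching"],
    }
    path.write_text(yaml.safe_dump(master, sort_keys=False))
    return path


def default_parameters() -> ParameterSet:
    """The bundled default parameterisation (2012 USD, Iranian setting)."""
    with resources.as_file(resources.files("mscea").joinpath("data/paper_2012.yaml")) as p:
        return load_parameters(p)
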