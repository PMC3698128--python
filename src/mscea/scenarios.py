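"""Analysis grid and elementary-effects sensitivity scenarios.

``run_grid`` evaluates every product against symptom management across the
four utility instruments and both discounting modes (48 ICER cells).
Sensitivity analysis is implemented as one-at-a-time and bivariate scenario
re-runs over explicit parameter paths, including the switch-destination
probability and the relapse episode duration — the two quantities the model
is parameterised for but that no source table prints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .model import CohortResults, MarkovCohortModel
from .outcomes import (
    CEResult,
    COST_EFFECTIVE,
    HIGHLY_COST_EFFECTIVE,
    NOT_COST_EFFECTIVE,
)
from .parameters import (
    INSTRUMENTS,
    ParameterSet,
    SwitchingPolicy,
    ValidationError,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_grid",
    "one_way_sweep",
    "bivariate_sweep",
    "set_parameter",
    "classification_diagnostic",
    "REFERENCE_PATTERN",
]


@dataclass
class ScenarioSpec:
    """One scenario: which strategies and valuation modes to evaluate."""

    product_ids: tuple[str, ...] | None = None   # None = all products
    instruments: tuple[str, ...] = INSTRUMENTS
    discounting_modes: tuple[bool, ...] = (False, True)
    switching_enabled: bool = True
    overrides: dict[str, object] = field(default_factory=dict)

    def resolve_products(self, params: ParameterSet) -> tuple[str, ...]:
        if self.product_ids is None:
            return tuple(p.id for p in params.products)
        known = {p.id for p in params.products}
        missing = set(self.product_ids) - known
        if missing:
            raise ValidationError(f"unknown products in scenario: {sorted(missing)}")
        return self.product_ids


@dataclass
class ScenarioResult:
    """Complete grid of incremental results, with provenance."""

    frame: pd.DataFrame
    fingerprint: str
    spec: ScenarioSpec

    def cell(self, strategy: str, instrument: str, discounted: bool) -> CEResult:
        f = self.frame
        sel = f[
            (f["strategy"] == strategy)
            & (f["instrument"] == instrument)
            & (f["discounted"] == discounted)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no unique cell for ({strategy}, {instrument}, {discounted})"
            )
        return sel.iloc[0]["result"]

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def check_complete(self) -> None:
        spec = self.spec
        expected = (
            len(self.frame["strategy"].unique())
            * len(spec.instruments)
            * len(spec.discounting_modes)
        )
        if len(self.frame) != expected:
            raise ValidationError(
                f"incomplete grid: {len(self.frame)} cells, expected {expected}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Plain-column view (no result objects), suitable for CSV export."""
        return self.frame.drop(columns=["result"])


def _apply_overrides(params: ParameterSet, overrides: dict[str, object]) -> ParameterSet:
    for path, value in overrides.items():
        params = set_parameter(params, path, value)
    return params


def run_scenario(params: ParameterSet, spec: ScenarioSpec) -> ScenarioResult:
    params = _apply_overrides(params, spec.overrides)
    product_ids = spec.resolve_products(params)
    comparator = MarkovCohortModel(params, None).run()
    rows = []
    for pid in product_ids:
        res = MarkovCohortModel(
            params, pid, switching_enabled=spec.switching_enabled
        ).run()
        for inst in spec.instruments:
            for discounted in spec.discounting_modes:
                ce = res.compare_to(comparator, inst, discounted)
                rows.append({**ce.to_dict(), "result": ce})
    frame = pd.DataFrame(rows)
    result = ScenarioResult(frame=frame, fingerprint=params.fingerprint(), spec=spec)
    result.check_complete()
    return result


def run_grid(
    params: ParameterSet,
    switching_enabled: bool = True,
    instruments: tuple[str, ...] = INSTRUMENTS,
    product_ids: tuple[str, ...] | None = None,
) -> ScenarioResult:
    """The full products x instruments x discounting grid of ICERs."""
    return run_scenario(
        params,
        ScenarioSpec(
            product_ids=product_ids,
            instruments=instruments,
            switching_enabled=switching_enabled,
        ),
    )


# ---------------------------------------------------------------------------
# parameter paths


def set_parameter(params: ParameterSet, path: str, value: object) -> ParameterSet:
    """Return a validated copy of ``params`` with one parameter replaced.

    Paths are dotted: ``config.<field>``, ``transitions.<class>.<field>``,
    ``utilities.<instrument>.<field>``, ``products.<id>.annual_drug_cost``,
    plus the virtual path ``switching.switch_prob`` which rebuilds the
    switching policy with the given total switch probability (split equally
    over the permitted targets).
    """
    new = params.copy()
    parts = path.split(".")
    try:
        if parts[0] == "config" and len(parts) == 2:
            if not hasattr(new.config, parts[1]):
                raise ValidationError(f"unknown config field {parts[1]!r}")
            setattr(new.config, parts[1], value)
        elif parts[0] == "switching" and parts[1:] == ["switch_prob"]:
            new.switching = SwitchingPolicy.with_switch_prob(
                new.products, float(value), new.switching.switch_window_cycles
            )
        elif parts[0] == "transitions" and len(parts) == 3:
            tp = new.transitions[parts[1]]
            if not hasattr(tp, parts[2]):
                raise ValidationError(f"unknown transition field {parts[2]!r}")
            setattr(tp, parts[2], value)
        elif parts[0] == "utilities" and len(parts) == 3:
            us = new.utilities[parts[1]]
            if parts[2] in us.utilities:
                us.utilities[parts[2]] = float(value)
            elif hasattr(us, parts[2]):
                setattr(us, parts[2], value)
            else:
                raise ValidationError(f"unknown utility field {parts[2]!r}")
        elif parts[0] == "products" and len(parts) == 3:
            product = new.product(parts[1])
            if not hasattr(product, parts[2]):
                raise ValidationError(f"unknown product field {parts[2]!r}")
            setattr(product, parts[2], value)
            if parts[2] == "annual_drug_cost":
                # keep the cost table consistent with the product price
                for key in new.costs.drug[product.id]:
                    if new.costs.drug[product.id][key] > 0:
                        new.costs.drug[product.id][key] = float(value)
        else:
            raise ValidationError(f"cannot resolve parameter path {path!r}")
    except KeyError as exc:
        raise ValidationError(
            f"parameter path {path!r}: unknown key {exc.args[0]!r}"
        ) from exc
    return new.validate()


def one_way_sweep(
    params: ParameterSet,
    target: str,
    values: list,
    spec: ScenarioSpec | None = None,
) -> tuple[list[tuple[object, ScenarioResult]], pd.DataFrame]:
    """Re-run the grid for each value of one parameter.

    All values are validated against the parameter's legal range before any
    grid is run.  Returns the per-value results and a long summary table of
    ICER vs value.
    """
    spec = spec or ScenarioSpec()
    staged = [(v, set_parameter(params, target, v)) for v in values]  # validate first
    results = []
    summary_rows = []
    for v, p in staged:
        res = run_scenario(p, replace(spec, overrides={}))
        results.append((v, res))
        for row in res.frame.itertuples():
            summary_rows.append(
                {
                    "target": target,
                    "value": v,
                    "strategy": row.strategy,
                    "instrument": row.instrument,
                    "discounted": row.discounted,
                    "icer": row.icer,
                    "who_class": row.who_class,
                }
            )
    return results, pd.DataFrame(summary_rows)


def bivariate_sweep(
    params: ParameterSet,
    targets: tuple[str, str],
    value_grid: tuple[list, list],
    spec: ScenarioSpec | None = None,
) -> dict[tuple[object, object], ScenarioResult]:
    """Full factorial re-run over two parameter paths."""
    spec = spec or ScenarioSpec()
    t1, t2 = targets
    v1s, v2s = value_grid
    staged = {}
    for v1 in v1s:
        for v2 in v2s:
            p = set_parameter(set_parameter(params, t1, v1), t2, v2)
            staged[(v1, v2)] = p
    return {key: run_scenario(p, spec) for key, p in staged.items()}


# ---------------------------------------------------------------------------
# calibration diagnostic: qualitative classification pattern

#: Reference classification pattern under literature / VAS / HUI3 utilities:
#: the copied IM IFNb-1a is highly cost-effective, Rebif, Betaferon and both
#: copied SC products are cost-effective, and Avonex is not cost-effective.
REFERENCE_PATTERN = {
    "cbp_im_1a": HIGHLY_COST_EFFECTIVE,
    "rebif": COST_EFFECTIVE,
    "betaferon": COST_EFFECTIVE,
    "cbp_sc_1a": COST_EFFECTIVE,
    "cbp_sc_1b": COST_EFFECTIVE,
    "avonex": NOT_COST_EFFECTIVE,
}

_PATTERN_INSTRUMENTS = ("literature", "vas", "hui3")


def pattern_match(
    result: ScenarioResult,
    discounted: bool,
    instruments: tuple[str, ...] = _PATTERN_INSTRUMENTS,
    pattern: dict[str, str] = REFERENCE_PATTERN,
) -> bool:
    """Does one grid slice reproduce the reference classification pattern?"""
    for inst in instruments:
        for pid, expected in pattern.items():
            ce = result.cell(pid, inst, discounted)
            if ce.who_class != expected:
                return False
    return True


def classification_diagnostic(
    params: ParameterSet,
    switch_probs: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
    durations: tuple[float, ...] = (0.0, 0.25, 0.5),
) -> pd.DataFrame:
    """Search the exposed (switch probability, relapse duration) ranges for
    settings whose grid reproduces the reference classification pattern.

    This is a calibration diagnostic, not an assertion: it reports, per
    setting and discounting mode, whether the qualitative pattern holds and
    what each product's WHO class is.
    """
    rows = []
    for sp in switch_probs:
        p1 = set_parameter(params, "switching.switch_prob", sp)
        for dur in durations:
            p2 = set_parameter(p1, "config.relapse_episode_duration_years", dur)
            grid = run_grid(p2)
            for discounted in (False, True):
                row = {
                    "switch_prob": sp,
                    "relapse_episode_duration_years": dur,
                    "discounted": discounted,
                    "matches_reference": pattern_match(grid, discounted),
                }
                for pid in REFERENCE_PATTERN:
                    row[f"class_{pid}"] = grid.cell(
                        pid, "literature", discounted
                    ).who_class
                rows.append(row)
    return pd.DataFrame(rows)
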