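"""Synthetic cross-sectional survey of MS patients, and its estimators.

The generator emulates the kind of 200-patient cross-sectional study the
model's utility and cost inputs come from: patients stratified by MS type
and EDSS band (including primary-progressive and unclassified patients, who
have no model state and are excluded from estimation), with instrument-level
utility responses (VAS, EQ-5D, HUI3) drawn around each stratum's true value
with truncated-normal noise, gamma-distributed annual resource-use costs
around the cost-table means, and past-year relapse counts.  Relapse utility
loss is elicited as a paired within-patient decrement.

``estimate_utilities`` / ``estimate_costs`` recover the generating inputs by
stratum means, exactly under zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import CostSet, UtilitySet, ValidationError

__all__ = [
    "EstimationError",
    "SurveyStratum",
    "SurveyDesign",
    "SyntheticSurvey",
    "TABLE3_DESIGN",
    "generate_survey",
    "estimate_utilities",
    "estimate_costs",
]

RESPONSE_INSTRUMENTS = ("vas", "eq5d", "hui3")

#: survey stratum -> model health state
_STRATUM_STATE = {
    ("rrms", "mild"): "rrms_mild",
    ("rrms", "mod"): "rrms_mod",
    ("rrms", "sev"): "rrms_sev",
    ("spms", "mod"): "spms_mod",
    ("spms", "sev"): "spms_sev",
}

_COST_ITEM_BLOCKS = ("other_direct_medical", "non_medical_direct", "indirect")


class EstimationError(ValueError):
    """A survey cannot support the requested estimate (e.g. empty stratum)."""


@dataclass(frozen=True)
class SurveyStratum:
    ms_type: str            # rrms | spms | ppms | unknown
    edss_band: str | None   # mild | mod | sev | None for ppms/unknown
    n: int
    age_mean: float
    age_sd: float
    frac_female: float
    frac_educated: float
    frac_employed: float

    @property
    def state_key(self) -> str | None:
        return _STRATUM_STATE.get((self.ms_type, self.edss_band))


@dataclass(frozen=True)
class SurveyDesign:
    strata: tuple[SurveyStratum, ...]

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.strata)


#: Default 200-patient design: RRMS 104/29/12 by EDSS band, SPMS 24/4,
#: plus 19 primary-progressive and 8 unclassified patients, with the
#: per-stratum demographics of the source survey.
TABLE3_DESIGN = SurveyDesign(
    strata=(
        SurveyStratum("rrms", "mild", 104, 29.0, 7.7, 80 / 104, 0.83, 0.37),
        SurveyStratum("rrms", "mod", 29, 36.0, 7.2, 24 / 29, 0.79, 0.48),
        SurveyStratum("rrms", "sev", 12, 36.6, 9.2, 10 / 12, 0.83, 0.0),
        SurveyStratum("spms", "mod", 24, 42.4, 6.7, 16 / 24, 0.83, 0.29),
        SurveyStratum("spms", "sev", 4, 46.0, 3.7, 2 / 4, 1.0, 0.0),
        SurveyStratum("ppms", None, 19, 41.8, 6.3, 10 / 19, 0.53, 0.0),
        SurveyStratum("unknown", None, 8, 34.5, 8.2, 6 / 8, 0.75, 0.13),
    )
)

#: Annual relapse rates used to draw past-year relapse counts (the model's
#: per-cycle natural-history rates halved; a nominal figure for non-model
#: strata).
DEFAULT_ANNUAL_RELAPSE_RATES = {"rrms": 1.02, "spms": 0.35, "ppms": 0.3, "unknown": 0.5}


@dataclass
class SyntheticSurvey:
    """Generated patient records plus the truth that generated them."""

    frame: pd.DataFrame
    design: SurveyDesign
    seed: int
    truth_utilities: dict[str, UtilitySet] | None = None
    truth_costs: CostSet | None = None
    noise: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "SyntheticSurvey":
        frame = pd.read_csv(path)
        return cls(frame=frame, design=SurveyDesign(strata=()), seed=seed)


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0.0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _gamma_around(rng, mean, cv, size):
    if mean == 0.0 or cv == 0.0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def generate_survey(
    truth_utilities: dict[str, UtilitySet],
    truth_costs: CostSet,
    design: SurveyDesign = TABLE3_DESIGN,
    utility_sd: float = 0.1,
    cost_cv: float = 0.5,
    seed: int = 0,
    annual_relapse_rates: dict[str, float] | None = None,
) -> SyntheticSurvey:
    """Draw a stratified synthetic survey around the given true inputs.

    Instrument responses are stratum truth plus truncated-normal noise on
    [0, 1]; relapse utility decrements are the instrument's true loss plus
    non-negative-truncated noise; cost items are gamma with the cost-table
    means and coefficient of variation ``cost_cv``.  Strata with no model
    state (PPMS / unknown) receive nominal moderate-band values and are
    excluded from estimation.
    """
    if utility_sd < 0 or cost_cv < 0:
        raise ValidationError("noise dispersions must be >= 0")
    for inst in RESPONSE_INSTRUMENTS:
        if inst not in truth_utilities:
            raise ValidationError(f"missing truth utility set for {inst!r}")
        truth_utilities[inst].validate()  # also rejects truths outside [0, 1]
    rates = annual_relapse_rates or DEFAULT_ANNUAL_RELAPSE_RATES
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for stratum in design.strata:
        if stratum.n < 0:
            raise ValidationError("stratum counts must be >= 0")
        n = stratum.n
        state = stratum.state_key or "rrms_mod"  # nominal values for non-model strata
        ages = _truncnorm(rng, stratum.age_mean, stratum.age_sd, 15.0, 90.0, n)
        female = rng.random(n) < stratum.frac_female
        educated = rng.random(n) < stratum.frac_educated
        employed = rng.random(n) < stratum.frac_employed
        relapses = rng.poisson(rates.get(stratum.ms_type, 0.5), size=n)
        responses = {}
        decrements = {}
        for inst in RESPONSE_INSTRUMENTS:
            us = truth_utilities[inst]
            responses[inst] = _truncnorm(rng, us.utilities[state], utility_sd, 0.0, 1.0, n)
            dec = _truncnorm(
                rng, us.relapse_utility_loss, utility_sd, 0.0, 1.0, n
            )
            decrements[inst] = np.where(relapses > 0, dec, np.nan)
        cost_cols = {}
        for block in _COST_ITEM_BLOCKS:
            items = getattr(truth_costs, block)[state]
            for item, mean in items.items():
                cost_cols[f"cost:{block}:{item}"] = _gamma_around(rng, mean, cost_cv, n)
        ms_for_relapse = "spms" if stratum.ms_type == "spms" else "rrms"
        rel_cost = _gamma_around(rng, truth_costs.relapse_cost[ms_for_relapse], cost_cv, n)
        rel_cost = np.where(relapses > 0, rel_cost, np.nan)
        for i in range(n):
            rows.append(
                {
                    "patient_id": pid + i,
                    "ms_type": stratum.ms_type,
                    "edss_band": stratum.edss_band,
                    "age": ages[i],
                    "sex": "F" if female[i] else "M",
                    "educated": bool(educated[i]),
                    "employed": bool(employed[i]),
                    "relapses_past_year": int(relapses[i]),
                    **{inst: responses[inst][i] for inst in RESPONSE_INSTRUMENTS},
                    **{
                        f"{inst}_relapse_decrement": decrements[inst][i]
                        for inst in RESPONSE_INSTRUMENTS
                    },
                    **{k: v[i] for k, v in cost_cols.items()},
                    "relapse_cost_per_episode": rel_cost[i],
                }
            )
        pid += n
    frame = pd.DataFrame(rows)
    return SyntheticSurvey(
        frame=frame,
        design=design,
        seed=seed,
        truth_utilities=truth_utilities,
        truth_costs=truth_costs,
        noise={"utility_sd": utility_sd, "cost_cv": cost_cv},
    )


def _model_strata(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for (ms, band), state in _STRATUM_STATE.items():
        sel = frame[(frame["ms_type"] == ms) & (frame["edss_band"] == band)]
        out[state] = sel
    return out


def estimate_utilities(
    survey: SyntheticSurvey,
) -> tuple[dict[str, UtilitySet], pd.DataFrame]:
    """Stratum-mean utility sets per elicitation instrument, with diagnostics.

    Returns one :class:`UtilitySet` per response instrument (VAS, EQ-5D,
    HUI3; a literature-review set is not elicitable from a survey) and a
    diagnostics table of per-stratum sample sizes and 95% CI half-widths,
    flagging the widest-interval stratum.
    """
    strata = _model_strata(survey.frame)
    empty = [state for state, sel in strata.items() if len(sel) == 0]
    if empty:
        raise EstimationError(
            f"cannot estimate utilities: empty strata {sorted(empty)}"
        )
    estimates = {}
    diag_rows = []
    for inst in RESPONSE_INSTRUMENTS:
        utilities = {}
        for state, sel in strata.items():
            vals = sel[inst].to_numpy()
            utilities[state] = float(np.clip(vals.mean(), 0.0, 1.0))
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            diag_rows.append(
                {
                    "instrument": inst,
                    "state": state,
                    "n": len(vals),
                    "mean": utilities[state],
                    "se": se,
                    "ci_halfwidth": 1.96 * se,
                }
            )
        dec = survey.frame[f"{inst}_relapse_decrement"].dropna()
        if len(dec) == 0:
            raise EstimationError(
                "cannot estimate relapse utility loss: no relapse-marked patients"
            )
        us = UtilitySet(
            instrument=inst,
            utilities=utilities,
            relapse_utility_loss=float(np.clip(dec.mean(), 0.0, 1.0)),
        )
        us.validate()
        estimates[inst] = us
    diagnostics = pd.DataFrame(diag_rows)
    widest = diagnostics.groupby("state")["ci_halfwidth"].mean().idxmax()
    diagnostics["widest_ci_stratum"] = diagnostics["state"] == widest
    return estimates, diagnostics


def estimate_costs(
    survey: SyntheticSurvey, reference: CostSet | None = None
) -> CostSet:
    """Stratum-mean cost blocks; per-relapse cost from relapse-marked records.

    Quantities a cross-sectional resource-use survey cannot observe (drug
    tariffs, NSAID prophylaxis, symptomatic co-medication rows) are carried
    over from ``reference`` (default: the survey's generating cost set).
    """
    reference = reference if reference is not None else survey.truth_costs
    if reference is None:
        raise EstimationError(
            "estimate_costs needs a reference cost set for non-surveyed blocks"
        )
    strata = _model_strata(survey.frame)
    empty = [state for state, sel in strata.items() if len(sel) == 0]
    if empty:
        raise EstimationError(f"cannot estimate costs: empty strata {sorted(empty)}")
    import copy

    est = copy.deepcopy(reference)
    for block in _COST_ITEM_BLOCKS:
        items = getattr(est, block)
        totals = getattr(est, f"{block}_total")
        for state, sel in strata.items():
            for item in items[state]:
                items[state][item] = float(sel[f"cost:{block}:{item}"].mean())
            totals[state] = sum(items[state].values())
    for ms in ("rrms", "spms"):
        if ms == "spms":
            sel = survey.frame[survey.frame["ms_type"] == "spms"]
        else:
            sel = survey.frame[survey.frame["ms_type"] == "rrms"]
        vals = sel["relapse_cost_per_episode"].dropna()
        if len(vals) == 0:
            raise EstimationError(
                f"cannot estimate relapse cost: no relapse-marked {ms} patients"
            )
        est.relapse_cost[ms] = float(vals.mean())
    est.validate()
    return est
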