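# Methods

## Model structure

The core is a discrete-time Markov cohort model over EDSS-banded disease
states (RRMS 1–3.5 / 4–6 / 6.5–9.5, SPMS 4–6 / 6.5–9.5, Death), expanded by
treatment status (on initial product / on once-switched product / off
treatment). The cohort enters at age 30 with all mass in (RRMS 1–3.5, on
product) and is projected through 15 cycles of 2 years. Structural
assumptions:

* RRMS→SPMS conversion cannot occur before cycle 3 (≈5 years after
  diagnosis) and happens within the same EDSS band; disability never
  improves; SPMS never reverts to RRMS; Death is absorbing.
* Only EDSS ≤ 6 states are interferon-eligible; mass progressing past
  EDSS 6 drops to off-treatment status (and drug/NSAID costs stop).
* Relapses do not change the EDSS state; they enter as expected counts per
  cycle (state occupancy × per-cycle relapse rate of the occupant's
  efficacy class), affecting QALYs and relapse costs only.
* Withdrawal is possible in every cycle. In cycles 1–3 a never-switched
  withdrawer may switch once, to one of the two alternatives in the same
  price class (brand↔brand, CBP/biosimilar↔CBP/biosimilar); from cycle 4
  on, and for prior switchers, withdrawal always means discontinuation.
  Reinitiation is never permitted.
* Mortality is identical across strategies (treatment does not alter the
  death risk) and sex-independent.

### Within-cycle event order

The order of competing risks inside a cycle is not dictated by the model's
sources; we fix it as death → withdrawal/switch → progression, each layer
conditioned on the previous one (multiplicative composition). Progression
after a same-cycle withdrawal or switch already uses the destination
status's efficacy class. The composition is validated by row-stochasticity
checks at 1e-12 on every transition-matrix row.

### Accrual and discounting

Costs and QALYs accrue from the state occupied at cycle start, for the full
2-year cycle; there is no half-cycle correction (a flag exists but is off
by default). Cycle *t* flows are discounted by `(1+r)^-(2t-1)` — i.e. to
the end of the cycle's first year — with r = 7.2 %/year for costs and
3 %/year for QALYs. An end-of-cycle convention (`(1+r)^-2t`) is available
via `ModelConfig.discount_convention`.

## Parameters

All inputs ship as a YAML master referencing one CSV per table
(`src/mscea/data/paper_2012.yaml`), in 2012 USD (12,260 IRR/USD):

* **Transitions / relapses / withdrawal** per efficacy class (natural
  history, IM IFNβ-1a, SC IFNβ-1a, SC IFNβ-1b), per 2-year cycle. The
  source table's EDSS band labels are internally inconsistent with the
  state list; we map "1–3" → EDSS 1–3.5, "3.5–6" → EDSS 4–6, "6≤" →
  EDSS 6.5–9.5, preserving the three-band structure. The SPMS-entry
  probability under IM IFNβ-1a equals natural history (0.43) while SC
  IFNβ-1a is 0.197; the asymmetry is consumed as printed.
* **Mortality**: age-banded probabilities (7.69 % at 30–35 rising to
  18.9 % at 66–70), interpreted by default as the death probability per
  2-year cycle for a patient whose age falls in the band; the table is not
  strictly monotone in age (36–40 dips to 7.61 %) and is consumed as
  printed. An alternative constant-hazard-within-band interpretation
  (`mortality_interpretation: band_hazard`) converts each band figure to
  the cycle length. Ages past the last band reuse its value (the horizon
  only reaches age 58, so this is a guard).
* **Utilities** per instrument (literature / VAS / EQ-5D / HUI3), five
  living-state weights in [0,1] with Death fixed at 0, plus a per-relapse
  utility loss (0.5 literature, 0.42 elicited instruments).
* **Costs** per state and year: IFNβ drug prices per product (zero in
  EDSS > 6), symptomatic co-medication (antidepressants use a higher rate
  in the first three cycles), NSAID side-effect prophylaxis per
  preparation, and itemised other-direct-medical, non-medical-direct and
  indirect blocks whose items sum to the printed block totals within 1 USD.
  Relapses cost 33 USD (RRMS) / 54 USD (SPMS) per episode. Where a product
  row aggregates several marketed items the printed figure is the
  market-share-weighted price and is consumed as final;
  `weighted_drug_cost` recomputes such aggregates when components are
  supplied.

### Quantities the sources do not print

Two inputs required by the mechanics are not tabulated anywhere and are
therefore explicit, sweepable parameters with documented defaults:

* **Switch-destination split** conditional on withdrawing in cycles 1–3:
  default uniform (1/3 to each permitted alternative, 1/3 off). The CLI
  (`--switch-prob`) and `switching.switch_prob` parameter path rebuild the
  policy with any total switch probability.
* **Relapse episode duration**: the per-relapse utility loss is a
  decrement *while the episode lasts*; applying it for a whole 2-year
  cycle would be implausible. Default 0.25 years (a ~3-month episode),
  configurable, exposed to sweeps.

The mortality-timing interpretation above is a third such choice. Absolute
ICER levels depend strongly on all three, while the orderings (every CBP
below its brand within a class; the copied IM IFNβ-1a cheapest per QALY;
the IM brand most expensive) are robust across the exposed ranges. The
`classification_diagnostic` scenario searches those ranges and reports,
rather than asserts, whether the reference WHO-class pattern (IM CBP highly
cost-effective, the SC products and brands cost-effective, the IM brand
not) is reached; under the bundled defaults it is not, and the diagnostic
prints the classes obtained instead.

## Synthetic survey generator

`generate_survey` emulates the cross-sectional study behind the utility and
cost inputs: 200 patients in the source strata (RRMS 104/29/12 by EDSS
band, SPMS 24/4, plus 19 PPMS and 8 unclassified patients who have no model
state and are excluded from estimation), with per-stratum age, sex,
education and employment frequencies. Instrument responses are stratum
truth plus truncated-normal noise on [0,1] (default SD 0.1); relapse
utility loss is elicited as a paired within-patient decrement (truth plus
non-negative-truncated noise) — a documented stand-in, since the original
elicitation is not described. Cost items are gamma-distributed around the
cost-table means (default CV 0.5); past-year relapse counts are Poisson at
half the per-cycle natural-history rate. Estimators are stratum means;
with zero noise they recover the generating inputs exactly, and the n = 4
SPMS-severe stratum is flagged as the widest confidence interval.

What the generator does *not* emulate: recruitment channels and
representativeness testing, EQ-5D/HUI3 tariff scoring (responses are drawn
directly on the index scale), within-patient correlation between
instruments, and cost–utility correlation. Passing recovery tests
therefore demonstrate estimator correctness under the stated noise
families, not robustness to real survey artefacts.

## Micro-simulation oracle

`microsimulate` realises n individual trajectories by sampling the same
per-cycle event probabilities (death, withdrawal/switch, progression) and
accruing the same start-of-cycle cost/QALY rules, without ever forming the
transition matrix — an independent check of the cohort engine. Agreement
is verified for all seven strategies at n = 100,000: discounted totals
within 3 Monte-Carlo SEs, and occupancy cells at the same 3-SE confidence
level applied family-wise across all state × cycle × strategy comparisons
(Bonferroni), since ~1,400 simultaneous per-cell 3-SE tests would flag
chance exceedances with near certainty even for a perfect implementation.
Relapse-related QALY decrements accrue linearly in the sampled relapse
count (no per-individual floor): the cohort engine's cycle-level floor at
zero never binds at the tabulated rates, and flooring individual cycles
would estimate a different (strictly larger) quantity.

## Numerical choices

* Cohort propagation uses explicit sequential accumulation rather than
  BLAS matmul, so zero-mass compartments contribute exactly nothing; the
  switching-disabled model variant is then bitwise identical to a run with
  switch probability zero.
* Transition rows are validated to sum to 1 within 1e-9 at composition and
  1e-12 at the matrix level; market shares must sum to 1 within 1e-9.
* ICERs are undefined (NaN, with a dominance flag where applicable) when
  the incremental QALY is non-positive; WHO boundaries classify into the
  milder category (exactly 1×GDP is cost-effective, exactly 3×GDP still
  cost-effective). Whole-dollar rounding happens only at render time.
* Determinism: the cohort model and scenario grids are seed-free and
  bit-reproducible; survey and micro-simulation draw from
  `numpy.random.default_rng(seed)` and are reproducible from (design,
  seed). Scenario results carry the SHA-256 fingerprint of the parameter
  bundle that produced them.

## Known limitations

* Efficacy inputs derive from trial follow-up data consumed as given; no
  uncertainty distributions are attached, so there is no probabilistic
  sensitivity analysis — only one-way and bivariate scenario re-runs.
* The mortality figures imply a heavy per-cycle death risk from age 30;
  their timing interpretation is ambiguous (see above) and materially
  affects absolute costs and QALYs, though much less the ICER orderings.
* Costs are a single national tariff snapshot (2012) with friction-cost
  indirect costs; no inflation or currency conversion is modelled.
* Adverse-effect disutilities are not modelled beyond withdrawal; relapse
  severity is homogeneous within MS type.
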