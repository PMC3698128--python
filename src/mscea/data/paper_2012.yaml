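# Default parameter bundle: societal-perspective cost-utility analysis of
# interferon-beta products for RRMS/SPMS in Iran, 2012 USD.
tables:
  mortality: table4_mortality.csv
  transitions: table5_transitions.csv
  utilities: table6_utilities.csv
  costs: table7_costs.csv

config:
  n_cycles: 15
  cycle_length_years: 2
  start_age: 30
  discount_rate_cost: 0.072
  discount_rate_qaly: 0.03
  discount_convention: first_year_end
  relapse_episode_duration_years: 0.25
  gdp_per_capita: 5810
  currency: USD-2012
  irr_per_usd: 12260
  mortality_interpretation: per_cycle
  half_cycle_correction: false
  seed: 0

# Six active strategies; the comparator (symptom management alone) is implicit.
# Where a strategy aggregates several marketed items, the listed drug cost is
# the market-share-weighted figure and is consumed as final.
products:
  - id: avonex
    label: "IM IFNb-1a (Avonex)"
    efficacy_class: im_ifnb1a
    price_class: brand
  - id: rebif
    label: "SC IFNb-1a 44mcg (Rebif)"
    efficacy_class: sc_ifnb1a
    price_class: brand
  - id: betaferon
    label: "SC IFNb-1b (Betaferon)"
    efficacy_class: sc_ifnb1b
    price_class: brand
  - id: cbp_im_1a
    label: "CBP IM IFNb-1a (Cinnovex 98% / Actovex 2%)"
    efficacy_class: im_ifnb1a
    price_class: cbp
  - id: cbp_sc_1a
    label: "CBP SC IFNb-1a (Recigen 87.5% / Actorif 12.5%)"
    efficacy_class: sc_ifnb1a
    price_class: cbp
  - id: cbp_sc_1b
    label: "CBP/BS SC IFNb-1b (Extavia 75% / Ziferon 12.5% / Actoferon 12.5%)"
    efficacy_class: sc_ifnb1b
    price_class: cbp

# Withdrawal in cycles 1..switch_window_cycles may be resolved into a once-only
# switch to one of the two same-price-class alternatives, or discontinuation.
# The destination split conditional on withdrawing is not tabulated anywhere;
# the bundled default is a uniform three-way split.
switching:
  switch_window_cycles: 3
  max_switches: 1
  split: uniform
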