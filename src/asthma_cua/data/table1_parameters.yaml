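# Base-case inputs of the published add-on tiotropium cost-utility model,
# 2023 US$ at COP 4,000 per US$, with the lower/upper ranges used in the
# sensitivity analyses.
#
# Digit-run parsing of the source table's concatenated columns (base/upper/lower):
#   "718953"       -> 71 / 89 / 53       drug cost per 4-week cycle
#   "384728"       -> 38 / 47 / 28       controlled-state annual cost; OCS burst per episode
#   "264833101986" -> 2648 / 3310 / 1986 ED visit per episode
#   "230288173"    -> 230 / 288 / 173    hospitalization per episode
#   "1.141"        -> 1.14               annual exacerbation rate (the trailing "1" is
#                                        unparseable; the alternative reading 1.141 is
#                                        recorded here and not used)
#
# Declared modelling assumptions (not printed in the source table):
#   * exacerbation severity split 0.40 / 0.35 / 0.25 (OCS burst / ED / hospitalization)
#   * asthma case fatality 0.01 per hospitalized exacerbation, 0 otherwise
#   * exacerbation-rate range = base +/- 25% (the rule stated for transition probabilities)
#   * adherence: 28% discontinue after 16 weeks (8 two-week cycles); the published
#     adherence row 61% (76%/57%) supplies the DSA range on the discontinuation
#     fraction via 1 - adherence -> 0.24 .. 0.43

costs:
  drug_per_4wk:                {base: 71,   lower: 53,   upper: 89}
  controlled_state_annual:     {base: 38,   lower: 28,   upper: 47}
  ocs_burst_per_episode:       {base: 38,   lower: 28,   upper: 47}
  ed_visit_per_episode:        {base: 2648, lower: 1986, upper: 3310}
  hospitalization_per_episode: {base: 230,  lower: 173,  upper: 288}

utilities:
  controlled:     {base: 0.740, lower: 0.56, upper: 0.93}
  decrement_ocs:  {base: 0.10,  lower: 0.08, upper: 0.13}
  decrement_ed:   {base: 0.15,  lower: 0.11, upper: 0.19}
  decrement_hosp: {base: 0.20,  lower: 0.15, upper: 0.25}

effect:
  rr_exacerbation: {base: 0.72, lower: 0.62, upper: 0.83}

events:
  exacerbation_annual_rate: {base: 1.14, lower: 0.855, upper: 1.425}
  split_ocs: 0.40
  split_ed: 0.35
  split_hosp: 0.25
  asthma_case_fatality_hosp: 0.01

adherence:
  discontinuation_fraction: {base: 0.28, lower: 0.24, upper: 0.43}
  waning_cycle: 8

econ:
  annual_discount_rate: {base: 0.05, lower: 0.00, upper: 0.06}
  wtp_per_qaly: 5180
  cycle_days: 14
  currency_cop_per_usd: 4000
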