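# Published summary tables of the assessment, shipped as reference fixtures.
# These are model OUTPUTS as printed in the source report; the package uses
# them for reproduction checks (scenario subtraction, budget totals,
# incremental costs) and for calibration targets.  All costs EUR.

# Annual hospitalizations for osteoporotic fractures, women 45+, Italy 2009.
hospitalizations:
  hip_femur: {admissions: 4653, total_cost: "14077146.05"}
  vertebral: {admissions: 2318, total_cost: "2549459.76"}
  other: {admissions: 3254, total_cost: "6297477.79"}

# Published discharge rates per 100,000 women aged 45+ (denominator never
# printed; back-solved populations are used only in tests, labelled as such).
discharge_rates_per_100k:
  all_fractures: 35.60
  hip_femur: 17.11

# Yearly fracture counts in the treated population, with-denosumab vs
# without-denosumab scenarios, and the printed avoided counts and savings.
scenario_fractures:
  hip:
    without: {2010: 36343, 2011: 37142, 2012: 37971, 2013: 38657}
    with: {2010: 36343, 2011: 37049, 2012: 37808, 2013: 38382}
    printed_avoided: {2011: 93, 2012: 163, 2013: 275}
    printed_saving_eur: {2011: 860000, 2012: 2042000, 2013: 3788000}
  vertebral:
    without: {2010: 21487, 2011: 21506, 2012: 21612, 2013: 21640}
    with: {2010: 21487, 2011: 21370, 2012: 21387, 2013: 21268}
    printed_avoided: {2011: 136, 2012: 225, 2013: 372}
    printed_saving_eur: {2011: 333000, 2012: 653000, 2013: 1139000}

# Budget impact of introducing denosumab, thousands EUR by cost category
# (negative = saving for the health service).  2010 is the pre-entry year.
budget_impact_keur:
  medications: {2011: -3766, 2012: -5854, 2013: -9385}
  inpatient: {2011: -1174, 2012: -2025, 2013: -3383}
  outpatient: {2011: -250, 2012: -420, 2013: -689}
  community: {2011: 0, 2012: -624, 2013: -1447}
  printed_total: {2011: -5190, 2012: -8923, 2013: -14904}

# Lifetime cost-effectiveness results (denosumab vs each comparator) for a
# 65-year-old cohort with T-score < -4 SD; discounted totals.  The printed
# differences and ICERs use unrounded internals, so equality on those cells
# is only asserted where the printed arithmetic closes.
cost_effectiveness:
  denosumab: {total_cost: 22399, qalys: 10.46}
  comparators:
    risedronate:
      total_cost: 21819
      qalys: 10.40
      printed_difference: 579
      printed_icer: 10302
    alendronate_generic:
      total_cost: 21621
      qalys: 10.41
      printed_difference: 778
      printed_icer: 18047
    alendronate_branded:
      total_cost: 21661
      qalys: 10.41
      printed_difference: 738
      printed_icer: 17133
    ibandronate:
      total_cost: 22238
      qalys: 10.38
      printed_difference: 161
      printed_icer: 2158
    strontium_ranelate:
      total_cost: 22394
      qalys: 10.39
      printed_difference: 5
      printed_icer: 69

# Pivotal-trial worked example: 36-month cumulative incidence of new
# vertebral fracture, denosumab vs placebo.
vertebral_trial:
  cumulative_incidence_treated: 0.023
  cumulative_incidence_placebo: 0.072
  printed_rr: 0.32
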