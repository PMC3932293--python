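# Default model inputs for the antiosteoporotic treatment models.
#
# Efficacy (relative risk reduction), compliance and market shares are the
# published model inputs; all monetary values are EUR and all percentages are
# stored as fractions.  Annual per-product drug prices are NOT published as
# unit prices anywhere; the `annual_drug_cost` entries below are a SYNTHETIC
# price vector back-solved so that price x (share x treated population) falls
# on the order of magnitude of the published yearly medication spend.  They
# are config-overridable and documented in docs/methods.md.

discount:
  annual_rate: 0.03
  cycle_length_years: 0.5

treatments:
  denosumab:
    label: "Denosumab"
    rrr_hip: 0.40
    rrr_vertebral: 0.68
    rrr_other: 0.20
    compliance: 0.85
    annual_drug_cost: 427.0          # synthetic, see header
    treatment_duration: 5.0
    offset_time: 1.0
  alendronate_branded:
    label: "Alendronate (Fosamax)"
    rrr_hip: 0.38
    rrr_vertebral: 0.44
    rrr_other: 0.17
    compliance: 0.60
    annual_drug_cost: 110.0
    treatment_duration: 5.0
    offset_time: 1.0
  alendronate_colecalciferol:
    label: "Alendronate plus cholecalciferol (Fosavance)"
    rrr_hip: 0.38
    rrr_vertebral: 0.44
    rrr_other: 0.17
    compliance: 0.60
    annual_drug_cost: 116.0
    treatment_duration: 5.0
    offset_time: 1.0
  alendronate_generic:
    label: "Generic alendronate"
    rrr_hip: 0.38
    rrr_vertebral: 0.44
    rrr_other: 0.17
    compliance: 0.60
    annual_drug_cost: 100.0
    treatment_duration: 5.0
    offset_time: 1.0
  risedronate:
    label: "Risedronate (Actonel)"
    rrr_hip: 0.26
    rrr_vertebral: 0.36
    rrr_other: 0.25
    compliance: 0.60
    annual_drug_cost: 143.0
    treatment_duration: 5.0
    offset_time: 1.0
  zoledronate:
    # Single canonical id for the branded once-yearly infusion; the source
    # tables inconsistently label it Aclasta/Actonel, hence the aliases.
    label: "Zoledronate (Aclasta)"
    aliases: ["Aclasta", "Actonel (zoledronate)"]
    rrr_hip: 0.41
    rrr_vertebral: 0.70
    rrr_other: 0.24
    compliance: 1.00
    annual_drug_cost: 377.0
    treatment_duration: 5.0
    offset_time: 1.0
  zoledronate_generic:
    label: "Generic zoledronate"
    rrr_hip: 0.41
    rrr_vertebral: 0.70
    rrr_other: 0.24
    compliance: 0.60
    annual_drug_cost: 250.0
    treatment_duration: 5.0
    offset_time: 1.0
  ibandronate:
    label: "Ibandronate oral (Bonviva)"
    rrr_hip: 0.00
    rrr_vertebral: 0.49
    rrr_other: 0.00
    compliance: 0.60
    annual_drug_cost: 179.0
    treatment_duration: 5.0
    offset_time: 1.0
  raloxifene:
    label: "Raloxifene (Evista)"
    rrr_hip: 0.00
    rrr_vertebral: 0.36
    rrr_other: 0.10
    compliance: 0.60
    annual_drug_cost: 155.0
    treatment_duration: 5.0
    offset_time: 1.0
  strontium_ranelate:
    label: "Strontium ranelate (Protelos)"
    rrr_hip: 0.15
    rrr_vertebral: 0.38
    rrr_other: 0.09
    compliance: 0.60
    annual_drug_cost: 228.0
    treatment_duration: 5.0
    offset_time: 1.0
  calcitonin:
    label: "Calcitonin (Miacalcic)"
    rrr_hip: 0.00
    rrr_vertebral: 0.00
    rrr_other: 0.00
    compliance: 0.60
    annual_drug_cost: 120.0
    treatment_duration: 5.0
    offset_time: 1.0
  teriparatide:
    label: "Teriparatide"
    rrr_hip: 0.75
    rrr_vertebral: 0.65
    rrr_other: 0.60
    compliance: 0.60
    annual_drug_cost: 2167.0
    treatment_duration: 5.0
    offset_time: 1.0
  pth:
    label: "PTH 1-84"
    rrr_hip: 0.35
    rrr_vertebral: 0.61
    rrr_other: 0.03
    compliance: 0.60
    annual_drug_cost: 1970.0
    treatment_duration: 5.0
    offset_time: 1.0

costs_utilities:
  unit_costs:
    hip: 8206.0
    vertebral: 2476.0
  other_fracture_costs:
    pelvis_other_femoral: 4575.0
    forearm: 2831.0
    ribs_sternum: 1022.0
    scapula_clavicle: 2962.0
    proximal_humerus: 4575.0
    tibia_fibula: 4929.0
  # Pooled "other fractures" state: equal-weight mix of the sub-table above
  # unless overridden here (weights need not be normalized).
  other_fracture_mix:
    pelvis_other_femoral: 1.0
    forearm: 1.0
    ribs_sternum: 1.0
    scapula_clavicle: 1.0
    proximal_humerus: 1.0
    tibia_fibula: 1.0
  utilities:
    hip: {first_year: 0.700, subsequent: 0.800}
    vertebral: {first_year: 0.590, subsequent: 0.929}
    # wrist 0.956 is published separately but wrist is pooled into "other"
    other: {first_year: 0.902, subsequent: null}   # null -> healthy utility
  wrist_utility_first_year: 0.956
  # Fracture-state utilities are absolute weights, so the fracture-free state
  # carries full health; it must dominate every fracture-state utility or
  # preventing fractures could perversely lose QALYs.
  healthy_utility: 1.0

market_shares:
  # fractions per product per calendar year; raw columns may sum to slightly
  # less than 1 because the source prints one decimal -- the loader
  # normalizes within a 1% tolerance.
  2010:
    denosumab: 0.000
    alendronate_branded: 0.097
    alendronate_colecalciferol: 0.159
    alendronate_generic: 0.277
    risedronate: 0.243
    zoledronate: 0.003
    ibandronate: 0.093
    raloxifene: 0.017
    strontium_ranelate: 0.098
    calcitonin: 0.002
    teriparatide: 0.009
    pth: 0.002
  2011:
    denosumab: 0.023
    alendronate_branded: 0.086
    alendronate_colecalciferol: 0.154
    alendronate_generic: 0.273
    risedronate: 0.246
    zoledronate: 0.004
    ibandronate: 0.090
    raloxifene: 0.017
    strontium_ranelate: 0.093
    calcitonin: 0.002
    teriparatide: 0.009
    pth: 0.002
  2012:
    denosumab: 0.052
    alendronate_branded: 0.082
    alendronate_colecalciferol: 0.142
    alendronate_generic: 0.274
    risedronate: 0.244
    zoledronate: 0.004
    ibandronate: 0.083
    raloxifene: 0.017
    strontium_ranelate: 0.089
    calcitonin: 0.001
    teriparatide: 0.009
    pth: 0.002
  2013:
    denosumab: 0.080
    alendronate_branded: 0.077
    alendronate_colecalciferol: 0.137
    alendronate_generic: 0.270
    risedronate: 0.243
    zoledronate: 0.004
    ibandronate: 0.079
    raloxifene: 0.017
    strontium_ranelate: 0.081
    calcitonin: 0.001
    teriparatide: 0.009
    pth: 0.002

budget_impact:
  years: [2010, 2011, 2012, 2013]
  population:
    # Women aged 45+; back-solved from the published hip discharge rate
    # (17.11 per 100,000 on 4,653 admissions => ~27.2M).  Band split and
    # growth are synthetic stand-ins for an official projection.
    base_year: 2010
    counts: {"45-64": 12900000, "65-74": 7100000, "75+": 7200000}
    annual_growth: 0.003
  # Published anchors: 60,000 denosumab patients in the first uptake year,
  # 150,000 in the third.
  denosumab_patient_anchors: {2011: 60000, 2013: 150000}
  # "Without denosumab" counterfactual: denosumab's share is redistributed to
  # the products whose spend it erodes, in proportion to their published
  # erosion (oral ibandronate and strontium ranelate).
  displaced_weights: {ibandronate: 0.24, strontium_ranelate: 0.76}
  # Per-fracture follow-on costs (unpublished; synthetic, config-overridable):
  # outpatient cost accrues in the event year as a fraction of the acute
  # tariff; community (nursing) cost accrues the year AFTER a hip fracture.
  outpatient_cost_fraction: 0.213
  community_cost_per_hip: 6700.0
  # Age mix of the treated population used to average age-specific hazards.
  age_mix: {55: 0.30, 70: 0.40, 80: 0.30}
  hazard_gradients: {hip: 0.05, vertebral: 0.03, other: 0.01}

cohort_background:
  # Synthetic background for the lifetime cohort model: a 65-year-old
  # high-risk cohort (T-score < -4 SD).  Documented in docs/methods.md.
  start_age: 65
  max_age: 110
  gompertz: {a: 6.0e-6, b: 0.11}
  six_month_hazards_at_65: {hip: 0.015, vertebral: 0.020, other: 0.015}
  hazard_gradients: {hip: 0.05, vertebral: 0.03, other: 0.01}
  excess_mortality_hip: 2.0
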