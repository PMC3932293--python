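# osteohta

Health-economic models for antiosteoporotic treatment of postmenopausal
women, built around the assessment of denosumab (60 mg subcutaneously every
six months) against the oral comparators used in Italian practice —
bisphosphonates, strontium ranelate, raloxifene and the parathormone
analogues.  The package is aimed at health-economics and HTA analysts who
want a tested, scriptable implementation of three standard calculators:

- **Lifetime cost-effectiveness** (`osteohta.markov_cea`): a seven-state,
  six-month-cycle Markov cohort model (healthy; hip/femoral fracture;
  post-hip; vertebral fracture; post-vertebral; other fracture; death).
  Treatment lowers fracture entry probabilities by each drug's relative
  risk reduction while efficacy lasts, compliance splits the cohort, and
  discounted costs and QALYs combine into
  `ICER = ΔCosts / ΔQALYs`
  with dominance handling, probabilistic sensitivity analysis and
  cost-effectiveness acceptability curves
  (`P[λ·ΔQ − ΔC > 0]` over PSA draws at willingness-to-pay λ).
- **Budget impact** (`osteohta.budget_impact`): demographic projection ×
  disease model × market-share scenario ("with denosumab" vs "without"),
  producing per-year fracture counts and payer costs in four categories
  (medications, inpatient, outpatient, community) and their deltas in
  thousands of euros.
- **Hospitalization burden** (`osteohta.hospital_costs`): DRG-tariffed
  admission records aggregated with cent-exact decimal arithmetic into
  per-fracture-type counts, costs, mean cost per admission, and discharge
  rates per 100,000 women.

Published model inputs (per-drug efficacy and compliance, unit costs and
utilities, market shares, the 2009 hospitalization table) ship as validated
fixtures; every unpublished background (life table, baseline fracture
hazards, population projection) is generated synthetically and
deterministically by `osteohta.synthetic_inputs`, with calibration to
published fracture counts.  See `docs/methods.md` for the full model
description and assumptions.

## Worked example

`examples/cost_effectiveness.py` runs the lifetime model for a 65-year-old
high-risk cohort (T-score < −4 SD) under the documented synthetic
background, solving denosumab's annual price so its lifetime cost exceeds
strontium ranelate's by 5 € (the published near-tie):

```
calibrated denosumab annual price: EUR 310.53

comparator;cost_intervention;cost_comparator;qalys_intervention;qalys_comparator;delta_cost;delta_qalys;icer_eur_per_qaly
risedronate;9,725;9,320;13.99;13.90;405;0.0922;4,393
alendronate_generic;9,725;9,084;13.99;13.93;641;0.0641;10,000
alendronate_branded;9,725;9,113;13.99;13.93;612;0.0641;9,540
ibandronate;9,725;9,706;13.99;13.88;19;0.1191;160
strontium_ranelate;9,725;9,720;13.99;13.89;5;0.1069;47
```

Each row compares denosumab with one comparator: discounted lifetime cost
per woman (EUR), discounted QALYs, their differences, and the incremental
cost-effectiveness ratio.  Denosumab gains QALYs everywhere (higher
anti-fracture efficacy and 85 % vs 60 % compliance) and every ICER sits
below a 30,000 €/QALY willingness-to-pay threshold; against strontium
ranelate the near-tie in cost drives the ICER to ~47 €/QALY.

The other examples are one capability each: `hospital_burden.py` (the 2009
burden table: 10,225 admissions, 22,924,083.60 €, mean 2,241.96 €, 35.60
discharges per 100,000), `budget_impact.py` (scenario fracture counts and
category deltas; the published totals are −5,190 / −8,923 / −14,904
thousand € for 2011–2013), `psa_ceac.py` (acceptability curve), and
`synthetic_backgrounds.py` (life table, calibrated hazards, projection).

A thin CLI wraps the same functions:

```sh
osteohta burden --out table2.csv
osteohta bim --out bim.csv
osteohta cea --out cea.csv
osteohta psa --n-draws 1000 --seed 1 --out ceac.csv
osteohta synth --seed 1 --out-dir backgrounds/
```

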