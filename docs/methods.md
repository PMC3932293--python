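# Methods

`osteohta` implements the computational core of a health-economic assessment
of denosumab for preventing osteoporotic fractures in postmenopausal women:
a lifetime Markov cohort cost-effectiveness model, a four-year budget-impact
model, and a hospitalization burden-of-illness calculator, together with
deterministic generators for the background inputs the assessment used but
never published.  This note records the models, their assumptions, the
defaults and why they were chosen, and what the synthetic backgrounds can
and cannot show.

## Markov cohort model

**States and cycles.** A cohort of women (base case: age 65, T-score
< −4 SD) is propagated in six-month cycles through seven health states:
healthy, hip/femoral fracture, post-hip, vertebral fracture,
post-vertebral, other (non-hip non-vertebral) fracture, and death.
Fracture states are one-cycle event tunnels.  Hip and vertebral events flow
into persistent post-fracture states; other fractures recover to healthy
after one cycle; death is absorbing and reachable from every state.
Re-fracture from the post states occurs at the treated baseline risk, and a
second hip fracture re-enters the hip event state.

Internally the engine tracks nine compartments: each post state is split
into a first-year tunnel cycle (months 6–12 after the event) and a
long-term compartment.  This lets the *first-year* utilities and the
*first-year* post-hip excess mortality span a full year on a six-month
grid, which a flat seven-state chain cannot represent.  The public state
vector merges each pair, recovering the seven reported states; occupancy
conservation (Σ = 1 within 1e−12) and monotone death are enforced every
cycle, and the engine is verified against explicit matrix powers of the
internal transition matrix.

**Transitions.** At age *a* the six-month fracture entry probabilities are
the baseline hazards scaled by `1 − RRR·w`, where RRR is the drug's relative
risk reduction for that site and `w ∈ [0, 1]` the efficacy weight.
Competing risks compose death-first: the cycle's death probability is
applied first and fracture risks act on survivors.  Purely additive rows
would exceed probability 1 at extreme ages once the post-hip mortality
multiplier saturates; death-first composition keeps every row stochastic,
is standard for cohort state-transition models, and coincides with additive
arithmetic when mortality is zero (as in the package's hand-checked
examples).  Rows that still fail to sum to 1 raise an error — the engine
never silently renormalizes.

**Treatment dynamics.** Efficacy is full (`w = 1`) during the treatment
duration, then decays linearly to zero over the offset time; the weight is
evaluated at the start of each cycle.  Compliance splits the cohort at
baseline: a compliant fraction receives full efficacy and drug cost for the
treatment duration, and a noncompliant fraction receives drug cost and
efficacy for six months, followed by the same offset decay.  Defaults:
treatment duration 5 years and offset 1 year for every product
(conventional practice for osteoporosis models; both are per-product
config fields and sensitivity variables).

**Outcomes.** Costs are payer-perspective and direct only: drug acquisition
(annual price × half-year per cycle, accrued by the alive fraction of each
arm while on treatment) plus acute fracture costs attached to the event
cycle.  QALYs accrue as occupancy × state utility × ½ year.  The hip and
vertebral event and first-year tunnels use the first-year utilities (0.700,
0.590), the long-term compartments the subsequent-year utilities (0.800,
0.929); the pooled other-fracture event cycle uses 0.902 and its survivors
return to the healthy utility.  The healthy state carries utility 1.0: the
published fracture-state utilities are absolute weights, and the
fracture-free state must dominate all of them (the largest is 0.929) or
preventing fractures could perversely lose QALYs.  Costs and QALYs in the
cycle starting `t` years out are discounted by `(1.03)^(−t)`; a half-cycle
correction (mid-cycle occupancy for continuous accruals) is available as a
flag and off in the base case.

**Incremental analysis.** ICER = ΔCosts/ΔQALYs.  A strategy that is cheaper
and at least as effective is flagged *dominant*, the reverse *dominated*; a
zero QALY difference with a nonzero cost difference yields an infinite ICER
flag rather than an exception.

**Probabilistic sensitivity analysis.** Each draw jointly resamples unit
costs (Gamma, CV 20 %), utilities and compliance (Beta moment-matched,
SD 0.05), relative risks (LogNormal with median at the base RR and log-SD
0.12, the value implied by the pivotal trial's vertebral confidence
interval), fracture-risk scale (Gamma, mean 1, CV 10 %), offset time
(Uniform 0.5–2 y), treatment duration (Uniform 3–7 y) and the post-hip
mortality multiplier (Uniform 1.5–2.5), then re-runs every strategy.
Out-of-domain draws (utility or probability above 1, infeasible hazard
scale) are rejected and resampled with the rejection count reported.  The
acceptability curve counts draws with strictly positive net monetary
benefit `λ·ΔQ − ΔC`; ties count as not cost-effective (conservative).

## Synthetic backgrounds

The assessment never published its life table, baseline fracture hazards,
post-fracture excess mortality, or population projection.  The package
generates them deterministically:

- **Mortality** is Gompertz (hazard `a·e^{b·age}`): two parameters, easily
  calibrated, monotone.  Defaults `a = 6e−6`, `b = 0.11` give a six-month
  death probability of ~0.4 % at 65 and a remaining life expectancy of
  ~21 years at 65, in the range of Italian women around 2010.  The
  half-cycle probability integrates the hazard exactly over the cycle,
  `q = 1 − exp(−(a/b)(e^{b(age+½)} − e^{b·age}))`, so the discrete survival
  curve coincides with the continuous Gompertz survival on the grid (a
  constant-within-cycle hazard would bias life expectancy by ~0.2 years).
  The terminal age (110) is forced to probability 1 to close the cohort.
- **Baseline fracture hazards** follow log-linear age gradients
  (`0.05/0.03/0.01` per year for hip/vertebral/other) around a reference
  probability at 65 that is *calibrated*: the root is solved so that
  applying the hazards to a given treated population (patient counts per
  product, each under its compliance-weighted efficacy, averaged over an
  age mix of 55/70/80 with weights 0.30/0.40/0.30) reproduces target annual
  fracture counts.  Zero targets give zero hazards; infeasible targets
  raise.  Only the product of hazard level and population size is
  identified — the calibration fixes it given the population.
- **Post-hip excess mortality** multiplies all-cause mortality by 2.0
  during the first year after a hip fracture (event cycle plus first
  post-hip cycle), 1.0 thereafter; vertebral and other fractures carry no
  excess by default.  Config-overridable and varied in the PSA.
- **Population projection**: geometric growth (0.3 %/year) over three age
  bands from a 2010 base of 27.2 M women 45+.  That base is *back-solved*
  from the published hip discharge rate (4,653 admissions at 17.11 per
  100,000), not taken from official statistics; the published overall rate
  implies a slightly different denominator (28.7 M), and both exceed the
  census figure — the package follows the printed rates and labels the
  denominators synthetic.

The cohort model's base-case background (six-month hazards at 65 of
0.015/0.020/0.015 for hip/vertebral/other) represents the severe high-risk
cohort of the base case and is deliberately harsher than the
population-calibrated hazards of the budget model.

**What passing tests show.** The backgrounds make the pipelines exercise
realistic magnitudes and reproduce every published quantity that is
arithmetically closed (burden table, scenario subtractions, category
totals, incremental cost cells).  They cannot reproduce published outputs
that depend on the assessment's unpublished internals — absolute lifetime
costs and QALYs, the printed ICERs (10,302; 18,047; 17,133; 2,158; 69
€/QALY) and PSA probabilities — and the package does not claim to.
Instead, a calibration demonstration shows the published *qualitative*
ordering is attainable: solving denosumab's (synthetic) annual price so
its discounted lifetime cost exceeds strontium ranelate's by 5 € — the
printed near-tie — yields an ICER of ~47 €/QALY against strontium
ranelate and places all five comparisons below 30,000 €/QALY with positive
QALY gains.

## Budget-impact model

Three components, four calendar years (2010–2013):

1. **Demographics**: the population projection above.
2. **Disease/treatment**: per-year treated totals = population × a treated
   rate.  The rate is calibrated so denosumab's patient counts honor the
   published anchors exactly (60,000 in 2011, 150,000 in 2013, given its
   2.3 %/8.0 % shares); intermediate years interpolate the implied treated
   totals geometrically.  The two anchors imply treated totals of 2.61 M
   (2011) and 1.88 M (2013) — the published inputs are mutually
   inconsistent on this point (fracture counts grow while implied treated
   totals shrink), and the package resolves it in favour of the exact
   anchors.
3. **Technology prediction**: the market-share table splits the treated
   total per product.  The *without-denosumab* counterfactual removes
   denosumab and redistributes its share to the products whose spend it
   erodes — oral ibandronate and strontium ranelate, weighted 0.24/0.76 in
   proportion to their published erosion — conserving the number of
   treated patients.

Expected fracture counts are deterministic: patients × age-averaged annual
fracture probability under each product's compliance-weighted efficacy (a
seeded Poisson sampling mode exists for uncertainty runs).  Costs fall into
four payer categories: medications (annual price, with noncompliant
patients paying half a year), inpatient (acute tariff per fracture),
outpatient (a configurable 21.3 % of the acute tariff in the event year),
and community (a configurable 6,700 € nursing cost per hip fracture
accruing the following year, which is why the community category is empty
in the first uptake year).  The outpatient fraction and community cost are
synthetic: the published split does not print its generating unit costs.

Budget impact is the with-minus-without delta per category and year,
reported in thousands of euros rounded half away from zero (negative =
saving), with the total computed before rounding so categories add up to
the total within the rounding unit.

**Known limitation — the medications sign.** Under patient conservation and
the synthetic price vector, the medications category computes as an
*increase*: denosumab (427 €/yr list) costs more per patient than the
displaced oral products (179–228 €/yr).  The published medications saving
implies a counterfactual in which the displaced products' spend grows
beyond what patient conservation allows (its printed erosion is ~490 € per
denosumab patient).  The fracture-related categories do compute as
savings, and all published-table reproductions operate on the printed
deltas, which are shipped as fixtures.

## Drug prices

Per-product annual prices are not published anywhere as unit prices.  The
packaged vector is back-solved from published yearly spend divided by
(share × implied treated population ≈ 2.6 M): e.g. generic alendronate
100 €, risedronate 143 €, ibandronate 179 €, strontium ranelate 228 €,
teriparatide 2,167 €.  Denosumab's 427 €/yr is back-solved from the
published first-year medications delta given 60,000 patients.  All prices
are config fields, and the cost-effectiveness demo replaces denosumab's
with the calibrated near-tie price described above.

## Hospitalization burden

Admission records (fracture type, DRG tariff, optional age band) are
aggregated with exact decimal arithmetic — cent sums never touch binary
floating point — so the published totals (10,225 admissions,
22,924,083.60 €, mean 2,241.96 €) are reproduced exactly.  The synthetic
record generator draws per-record tariffs from a Gamma shape (CV 0.5),
scales them to the per-type cost marginal and distributes residual cents by
largest remainder, so per-type counts and cost sums match any given
marginals to the cent.  Discharge rates are admissions/population ×
100,000, two decimals.

## Numerical choices

- Conservation tolerance 1e−12 per cycle; transition rows are validated,
  never renormalized (roundoff below 1e−12 is clamped to zero on the
  remainder term only).
- Hazard calibration uses bracketed root-finding (`brentq`) with the upper
  bracket set by the probability-1 feasibility bound; convergence is
  re-checked to 1e−6 relative.
- Degenerate inputs: an all-dead initial vector is a fixed point; zero
  hazards and mortality hold the cohort healthy until the horizon; a
  trajectory truncates early once cumulative death reaches 1 − 1e−9.
- Market-share columns are normalized at load (printed rounding leaves
  some columns at 99.9 %) and rejected beyond a 1 % tolerance; re-loading
  already-normalized shares is exact.
- Reporting rounds thousands of euros half away from zero, matching the
  published sign and rounding convention.

## Problem sizes

Default runs propagate 90 six-month cycles (age 65–110) per strategy arm;
the packaged acceptance run uses 2,000 PSA draws over three strategies and
completes in seconds on one CPU.  The budget model is closed-form per year
and instantaneous.
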