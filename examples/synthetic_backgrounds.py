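"""Synthetic background inputs: life table, fracture hazards, population.

The assessment never published its mortality, baseline fracture risks or
population projection, so the package generates them: Gompertz mortality,
log-linear age gradients for fracture hazards calibrated to chosen annual
fracture counts, and a geometric population projection.
"""

from osteohta.parameters import TreatmentProfile
from osteohta.synthetic_inputs import (
    CalibrationExposure,
    life_expectancy,
    make_baseline_hazards,
    make_life_table,
    make_population_projection,
    treated_annual_probability,
)

life = make_life_table(gompertz_a=6.0e-6, gompertz_b=0.11)
print(f"6-month death probability at 65: {life.q(65):.4f}, at 85: {life.q(85):.4f}")
print(f"remaining life expectancy at 65: {life_expectancy(life, 65):.1f} years")

untreated = TreatmentProfile(
    name="untreated", rrr_hip=0.0, rrr_vertebral=0.0, rrr_other=0.0,
    compliance=1.0, annual_drug_cost=0.0,
)
exposure = CalibrationExposure(
    product_patients={"untreated": 2_600_000}, profiles={"untreated": untreated}
)
hazards = make_baseline_hazards(
    {"hip": 36_343, "vertebral": 21_487, "other": 25_416}, exposure
)
print(f"\ncalibrated 6-month hip probability at 65: {hazards.six_month('hip', 65):.5f}")
print(f"implied annual hip probability (age-mix averaged): "
      f"{treated_annual_probability(hazards, 'hip', untreated):.5f}")
print("-> 2.6M treated women then produce the target 36,343 hip fractures/year.")

proj = make_population_projection(
    {"45-64": 12_900_000, "65-74": 7_100_000, "75+": 7_200_000}, annual_growth=0.003
)
for year in proj.years():
    print(f"women 45+ in {year}: {proj.total(year):,.0f}")
print("The projection grows geometrically at 0.3%/year from the back-solved base.")
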