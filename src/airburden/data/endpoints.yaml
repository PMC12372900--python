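# Default endpoint registry: concentration-response parameters per health
# endpoint. Log-linear entries carry published hazard ratios per fixed
# increment with 95% confidence bounds; unit risks are lifetime excess
# cancer risks per 1 ug/m3. The PM2.5-mortality entry is a SYNTHETIC
# tabulated curve: a concave (supralinear) stand-in spanning the
# 2.5-83 ug/m3 domain of published low+high hybrid curves, shipped so the
# pipeline runs end to end; substitute a published curve's nodes for a
# production assessment.
lifespan_years: 76.4

endpoints:
  pm25_mortality:
    pollutant: PM2.5
    cause: non_accidental_mortality
    population_base: population
    age_range: [25, 200]
    units: ug/m3
    model: piecewise
    curve:
      concentrations: [2.5, 5.0, 8.0, 12.0, 17.7, 25.0, 35.0, 50.0, 65.0, 83.0]
      rr_central: [1.0, 1.0268, 1.0526, 1.0801, 1.1109, 1.1414, 1.1736, 1.2099, 1.2377, 1.2643]
      rr_low:     [1.0, 1.0228, 1.0447, 1.0681, 1.0943, 1.1202, 1.1476, 1.1784, 1.2020, 1.2247]
      rr_high:    [1.0, 1.0308, 1.0605, 1.0921, 1.1275, 1.1626, 1.1996, 1.2414, 1.2734, 1.3039]

  pm25_preterm_birth:
    pollutant: PM2.5
    cause: preterm_birth
    population_base: births
    units: ug/m3
    model: loglinear
    rr: [1.12, 1.06, 1.19]      # per increment, central/low/high
    increment: 10.0             # ug/m3
    counterfactual: 2.5

  no2_mortality:
    pollutant: NO2
    cause: non_accidental_mortality
    population_base: population
    age_range: [65, 200]        # elderly; coefficient adjusted for PM2.5 co-exposure
    units: ppb
    model: loglinear
    rr: [1.046, 1.044, 1.049]
    increment: 10.0             # ppb
    counterfactual: 2.0

  no2_asthma:
    pollutant: NO2
    cause: asthma_incidence
    population_base: population
    age_range: [1, 18]          # childhood-onset asthma
    units: ppb
    model: loglinear
    rr: [1.26, 1.10, 1.37]
    increment: 10.0
    counterfactual: 2.0

  o3_copd_mortality:
    pollutant: MDA8_O3
    cause: copd_mortality
    population_base: population
    age_range: [0, 200]         # all ages
    units: ppb
    model: loglinear
    rr: [1.06, 1.03, 1.10]
    increment: 10.0
    counterfactual: 32.4

# Lifetime excess cancer risk per person per 1 ug/m3 continuous exposure.
# No counterfactual applies to these.
unit_risks:
  formaldehyde: 1.1e-5
  acetaldehyde: 2.2e-6
  benzene: 7.8e-6
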