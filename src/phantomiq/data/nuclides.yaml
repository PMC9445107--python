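# Physical constants of common PET nuclides.
#
# beta_yield        : positron branching fraction (main branch; Ga-68's minor
#                     1.1% branch at 822 keV endpoint energy is not included)
# half_life_min     : physical half-life in minutes
# e_max_kev         : maximum (endpoint) beta+ energy in keV
# e_mean_kev        : average beta+ energy in keV
# range_max_water_mm: maximum positron range in water in mm
# range_mean_water_mm: mean positron range in water in mm
nuclides:
  F18:
    beta_yield: 0.967
    half_life_min: 109.8
    e_max_kev: 633.5
    e_mean_kev: 249.3
    range_max_water_mm: 2.4
    range_mean_water_mm: 0.6
  Ga68:
    beta_yield: 0.880
    half_life_min: 67.6
    e_max_kev: 1899.1
    e_mean_kev: 836.0
    range_max_water_mm: 9.2
    range_mean_water_mm: 3.5
  Cu64:
    beta_yield: 0.174
    half_life_min: 762.0
    e_max_kev: 653.1
    e_mean_kev: 278.0
    range_max_water_mm: 2.5
    range_mean_water_mm: 0.7
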