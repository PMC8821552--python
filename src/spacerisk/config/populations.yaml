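# Preset synthetic-population specifications: four U.S. racial/ethnic
# groups x two sexes.  Calibration targets are published 2018 life
# expectancies at birth and 2014-2018 delay-adjusted age-adjusted total
# cancer incidence rates per 100,000 (SEER-style standardisation).
api_female:      {population: api,      sex: female, life_expectancy: 86.0, age_adjusted_total: 328.2}
api_male:        {population: api,      sex: male,   life_expectancy: 81.0, age_adjusted_total: 311.2}
black_female:    {population: black,    sex: female, life_expectancy: 78.0, age_adjusted_total: 400.2}
black_male:      {population: black,    sex: male,   life_expectancy: 71.3, age_adjusted_total: 516.1}
hispanic_female: {population: hispanic, sex: female, life_expectancy: 84.3, age_adjusted_total: 355.9}
hispanic_male:   {population: hispanic, sex: male,   life_expectancy: 79.1, age_adjusted_total: 371.0}
white_female:    {population: white,    sex: female, life_expectancy: 81.1, age_adjusted_total: 460.2}
white_male:      {population: white,    sex: male,   life_expectancy: 76.2, age_adjusted_total: 520.4}
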