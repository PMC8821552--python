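# 940-day Mars design reference mission: 400 days total transit plus
# 540 days on the surface with atmospheric flux attenuation.
mission:
  name: mars-940d
  solar_condition: average solar minimum
  shield_label: 20 g/cm^2 aluminum
  dose_rate_mgy_per_day: 0.4
  segments:
    - {label: transit, duration_days: 400, attenuation: 1.0}
    - {label: surface, duration_days: 540, attenuation: 0.5}
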