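# 1-year free-space GCR exposure near average solar minimum, behind a
# nominal 20 g/cm^2 aluminum shield (synthetic parametric spectrum).
mission:
  name: gcr-1yr-solarmin
  solar_condition: average solar minimum
  shield_label: 20 g/cm^2 aluminum
  dose_rate_mgy_per_day: 0.4
  segments:
    - {label: free space, duration_days: 365, attenuation: 1.0}
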