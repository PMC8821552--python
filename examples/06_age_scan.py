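"""Lifetime risk versus age at exposure, 20 to 60 years.

Later exposure leaves fewer susceptible years before the age-100 cutoff and
deeper competing mortality, so REIC falls with exposure age for every
population; the female decline steepens above 40 as the breast-cancer
window closes.
"""

from spacerisk.reporting import RunConfig, age_scan

ages = range(20, 61, 5)
for name in ("white_female", "white_male"):
    table = age_scan(RunConfig(population=name), ages)
    print(f"\n{name}")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
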