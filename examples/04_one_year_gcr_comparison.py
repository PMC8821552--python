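"""Compare lifetime risks across populations for a 1-year GCR exposure.

Runs the targeted-effects model for all eight presets (exposure at age 35,
average solar minimum, nominal 20 g/cm^2 aluminum shielding) and ranks them
by total REIC.  The comparative structure -- White females highest, API and
Hispanic males lowest, females above males within every group, Blacks below
Whites despite similar cancer rates because of shorter life expectancy --
is the point; absolute percentages depend on the placeholder quality-factor
calibration.
"""

from spacerisk.reporting import RunConfig, compare_populations
import spacerisk as sr

configs = [RunConfig(population=name, scenario="gcr-1yr-solarmin", mode="TE",
                     exposure_age=35.0)
           for name in sorted(sr.load_preset_specs())]
table = compare_populations(configs)
cols = ["rank", "population", "total_reic_pct", "total_reid_pct"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{v:.2f}"))

print("\ntotal_reic_pct / total_reid_pct: lifetime risk of exposure-induced")
print("cancer / cancer death, percent, per tissue-summed relative-risk transfer.")
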