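"""Excess-relative-risk diagnostics from the LSS parameter registry.

Prints, per tissue with both-sex entries, the female-to-male ERR ratio at
the reference point (1 Gy, attained age 70, exposure age 30) -- which
reduces to rho_F / rho_M under the shared-modifier model -- and the percent
decline of ERR per decade of age at exposure, 100*(1 - e^{10*gamma}).
A negative decline means risk coefficients rise with later exposure.
"""

import spacerisk as sr

registry = sr.ERRRegistry.default()
both_sex = [t for t in ("all_solid", "leukemia", "lung", "stomach", "colon",
                        "liver", "urinary_bladder", "esophagus", "brain",
                        "pancreas", "thyroid", "other")]

print(f"{'tissue':<16} {'F/M ratio':>9} {'% decline/decade':>17}")
for tissue in both_sex:
    ratio = sr.fm_ratio(tissue, registry)
    gamma = registry.get(tissue, "male").gamma
    decline = sr.percent_decline_per_decade(gamma)
    print(f"{tissue:<16} {ratio:>9.2f} {decline:>17.1f}")

print("\nExample: colon F/M = 0.50/0.77 = 0.65 (males at higher relative")
print("risk), and its gamma = -0.0274/yr gives a 24% decline per decade.")
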