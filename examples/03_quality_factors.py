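"""Track-structure quality scaling for representative GCR ions.

For each ion the table lists the kinetic energy, LET in water, the
track-core weight P(Z,E) and the gamma-ray-relative scaling factor R_QF
(solid-cancer parameter set, DDREF = 2).  High-energy protons sit in the
low-LET limit R_QF -> 1/DDREF; iron near its LET peak carries quality
factors of a few tens.  The last block audits the synthetic GCR flux: its
recomputed absorbed-dose rate must match the 0.4 mGy/day calibration target.
"""

import spacerisk as sr
from spacerisk.quality import default_qf_params

qf = default_qf_params("solid")
print(f"{'ion':<4} {'E (MeV/u)':>9} {'LET (keV/um)':>13} {'P':>8} {'R_QF':>7}")
for label, z, e in [("H", 1, 2000.0), ("H", 1, 250.0), ("He", 2, 250.0),
                    ("O", 8, 600.0), ("Si", 14, 600.0), ("Fe", 26, 600.0),
                    ("Fe", 26, 250.0)]:
    let = sr.let_water(z, e)
    p = sr.p_function(z, e, qf)
    rq = sr.r_qf(z, e, qf)
    print(f"{label:<4} {e:>9.0f} {let:>13.2f} {p:>8.3f} {rq:>7.2f}")

flux = sr.make_gcr_flux(0.4)
print(f"\nGCR flux audit: absorbed-dose rate = {flux.absorbed_dose()*1e3:.4f} mGy/day "
      f"(target 0.4), total fluence = {flux.total_fluence:.4f} /um^2/day")
h = sr.gamma_equivalent_dose(flux, qf, "TE")
print(f"gamma-equivalent hazard rate (TE): {h*1e3:.3f} mGy-eq/day "
      f"-> effective scaling {h/flux.absorbed_dose():.2f}")
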