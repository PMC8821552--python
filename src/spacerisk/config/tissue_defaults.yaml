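# Default tissue composition for the synthetic cancer-rate generator.
#
# tissue_mix: fraction of the age-adjusted total incidence attributed to each
# site, per sex.  These are coarse, editable approximations of U.S. site
# distributions (breast/prostate dominant, lung and colorectal next, a large
# remainder group); they are NOT registry truth and exist so the generated
# tables have a realistic site structure.  Fractions must sum to 1 per sex.
tissue_mix:
  female:
    breast: 0.260
    lung: 0.115
    colon: 0.075
    thyroid: 0.075
    ovary: 0.025
    pancreas: 0.032
    liver: 0.012
    stomach: 0.015
    urinary_bladder: 0.022
    brain: 0.012
    esophagus: 0.004
    leukemia: 0.035
    other: 0.318
  male:
    prostate: 0.220
    lung: 0.130
    colon: 0.090
    urinary_bladder: 0.065
    liver: 0.025
    stomach: 0.018
    pancreas: 0.032
    brain: 0.013
    esophagus: 0.011
    thyroid: 0.020
    leukemia: 0.045
    other: 0.331

# Ratio of mortality to incidence per tissue (survival proxy); must lie in
# (0, 1/1.1] so generated tables already satisfy the mortality-consistency
# constraint without correction.
mortality_to_incidence:
  lung: 0.55
  stomach: 0.50
  colon: 0.40
  liver: 0.72
  urinary_bladder: 0.20
  esophagus: 0.85
  brain: 0.65
  pancreas: 0.85
  breast: 0.18
  ovary: 0.60
  prostate: 0.17
  thyroid: 0.07
  other: 0.35
  leukemia: 0.55

# Power-law onset shapes for age-specific incidence:
#   lambda(a) = A * max(a - onset, 0)^power
# Onset ages and powers are chosen so most site curves put their mass at
# ages 50-80 (screening-era adult cancers), breast rises early and flat,
# prostate late and steep, thyroid nearly flat from adolescence.
# Powers/onsets target the familiar median diagnosis ages (breast ~62,
# prostate ~66, lung ~70, colorectal ~66, thyroid ~50, remainder ~60 --
# the remainder pools young-adult sites like melanoma, kidney, lymphoma),
# together with the old-age roll-off applied in code.
incidence_shape:
  lung: {onset: 30, power: 4.5}
  stomach: {onset: 25, power: 3.5}
  colon: {onset: 20, power: 3.0}
  liver: {onset: 30, power: 3.5}
  urinary_bladder: {onset: 30, power: 4.0}
  esophagus: {onset: 30, power: 3.8}
  brain: {onset: 0, power: 1.5}
  pancreas: {onset: 30, power: 3.8}
  breast: {onset: 20, power: 2.0}
  ovary: {onset: 20, power: 2.4}
  prostate: {onset: 40, power: 5.0}
  thyroid: {onset: 10, power: 1.2}
  other: {onset: 15, power: 2.0}
  # leukemia uses a dedicated bimodal childhood/old-age curve in code
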