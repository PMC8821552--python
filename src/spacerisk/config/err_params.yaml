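# Excess-relative-risk parameters per tissue and sex, from published Life
# Span Study incidence analyses (solid cancers and leukemia excluding CLL).
# rho: ERR per Gy at attained age 70 for exposure at age 30.
# eta: attained-age power, shared between sexes.
# gamma: age-at-exposure coefficient per year, shared between sexes; omitted
#        where no trend was reported (treated as 0).
# upsilon: time-since-exposure power (leukemia only).
# ci_*: 95% confidence intervals where reported.
# Thyroid uses the external-report (BEIR VII style) parameterisation: same
# functional form, exposure-age coefficient per year.
# Uterine cancer is excluded: its estimated contribution is small.
all_solid:
  form: solid
  rho: {male: 0.33, female: 0.60}
  ci_rho: {male: [0.25, 0.42], female: [0.49, 0.72]}
  eta: -1.66
  ci_eta: [-2.11, -1.2]
  gamma: 0.019
leukemia:
  form: leukemia
  rho: {male: 0.79, female: 0.79}          # shared between sexes
  ci_rho: {male: [0.03, 1.93], female: [0.03, 1.93]}
  eta: -1.09
  ci_eta: [-2.01, -0.27]
  upsilon: -0.81
  ci_upsilon: [-1.31, -0.28]
lung:
  # zero-smoking limit of the generalized multiplicative smoking model
  form: solid
  rho: {male: 0.42, female: 1.2}
  ci_rho: {male: [0.16, 0.84], female: [0.74, 1.75]}
  eta: -2.5
  ci_eta: [-4.3, -0.71]
  gamma: -0.007
stomach:
  form: solid
  rho: {male: 0.21, female: 0.45}
  eta: -1.93
  ci_eta: [-2.94, -0.82]
colon:
  form: solid
  rho: {male: 0.77, female: 0.50}
  ci_rho: {male: [0.36, 1.3], female: [0.2, 0.9]}
  eta: -3.63
  ci_eta: [-6.17, -1.14]
  gamma: -0.0274
liver:
  form: solid
  rho: {male: 0.46, female: 0.70}
  ci_rho: {male: [0.19, 0.83], female: [0.29, 1.23]}
  eta: -1.1
  ci_eta: [-3.3, 1.3]
  gamma: -0.027
urinary_bladder:
  form: solid
  rho: {male: 0.64, female: 2.2}
  ci_rho: {male: [0.18, 1.2], female: [1.2, 3.5]}
  eta: -0.43
  ci_eta: [-2.8, 2.4]
esophagus:
  form: solid
  rho: {male: 0.30, female: 0.30}          # shared between sexes
  ci_rho: {male: [0.05, 0.65], female: [0.05, 0.65]}
brain:
  form: solid
  rho: {male: 2.46, female: 0.77}
  ci_rho: {male: [1.0, 4.89], female: [0.05, 1.95]}
  eta: -1.31
  ci_eta: [-3.23, 0.82]
  gamma: 0.028
pancreas:
  form: solid
  rho: {male: 0.13, female: 0.77}
  ci_rho: {male: [-0.26, 0.75], female: [0.16, 1.56]}
breast:
  form: solid
  rho: {female: 1.12}
  ci_rho: {female: [0.73, 1.59]}
  eta: -1.5
  ci_eta: [-2.6, -0.4]
  gamma: 0.0049
ovary:
  form: solid
  rho: {female: 0.30}
  ci_rho: {female: [-0.22, 1.11]}
prostate:
  form: solid
  rho: {male: 0.57}
  ci_rho: {male: [0.21, 1.0]}
thyroid:
  form: solid
  rho: {male: 0.53, female: 1.05}
  ci_rho: {male: [0.14, 2.0], female: [0.28, 3.9]}
  gamma: -0.083
other:
  # remainder group, external-report parameterisation
  form: solid
  rho: {male: 0.75, female: 1.08}
  ci_rho: {male: [0.31, 1.33], female: [0.56, 1.8]}
  eta: -0.79
  ci_eta: [-2.4, 1.0]
  gamma: 0.023
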