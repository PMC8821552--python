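# Methods

`spacerisk` computes lifetime risks of exposure-induced cancer (REIC) and
exposure-induced cancer death (REID) for charged-particle space exposures,
comparing populations under a multiplicative (relative-risk, RR) transfer
model. This note records the model, its discretization, the defaults, and
what the synthetic inputs do and do not represent.

## Lifetime risk model

The instantaneous radiogenic incidence rate for tissue T at attained age
*a* after an exposure at age *a*<sub>E</sub> with gamma-equivalent hazard
scalar *H*<sub>T</sub> (Gy) is

λ<sub>IT</sub>(a<sub>E</sub>, a, H<sub>T</sub>) = ERR<sub>T</sub>(a, a<sub>E</sub>) · λ<sub>0IT</sub>(a) · H<sub>T</sub>,

where λ<sub>0IT</sub> is the background incidence of the population under
study — the RR transfer assumption. The radiogenic mortality rate scales
the incidence rate by the background mortality-to-incidence ratio
λ<sub>0MT</sub>(a)/λ<sub>0IT</sub>(a). REIC folds the incidence rate with
the background survival function S<sub>0</sub>(t) and the probability of
having escaped radiation cancer death at earlier ages:

REIC = Σ<sub>j</sub> ∫<sub>a<sub>Ej</sub></sub><sup>100</sup> dt λ<sub>Ij</sub>(t) S<sub>0</sub>(t) exp(−Σ<sub>k</sub> ∫<sub>a<sub>Ek</sub></sub><sup>t</sup> dz λ<sub>Mk</sub>(z)),

summing over exposure events j; REID places λ<sub>M</sub> in the outer
integrand. Radiogenic contributions are zero within a hard minimum latency
of 5 years for solid cancers and 2 years for leukemia (no phase-in ramp; a
1-year leukemia latency is sometimes quoted and is configurable). Sums and
expectations terminate at age 100. S<sub>0</sub>(t) enters unconditionally,
not renormalised to survival at the exposure age. The lower bound of the
competing-mortality (inner) integral is each event's own exposure age by
default; truncating instead at the outer event's age is exposed via
`inner_bound="outer"` (the two coincide for single exposures).

**Discretization.** Integer ages 0..100; rates piecewise-constant over
[a, a+1); annual left-Riemann sums. This convention is exact, not
approximate, in the sense that the test oracle (an independent brute-force
enumeration of the double sum) reproduces the engine to 1e-10 relative.
Survival follows S<sub>0</sub>(a) = exp(−Σ<sub>k&lt;a</sub> h(k))
(exponential-within-year), so for a constant hazard the discrete life
expectancy equals the continuous closed form (1 − e<sup>−100μ</sup>)/μ
exactly. Rates are stored per 100,000 person-years and converted to per
person-year in exactly one function.

The competing-radiation-mortality exponential is a sub-percent correction
below ~0.1 Gy-equivalent and grows with dose; dropping it can only increase
REIC (both verified by the enumeration oracle).

## Excess relative risk

Solid cancers: ERR = ρ<sub>sex</sub>·D·(a/70)<sup>η</sup>·e<sup>γ(a<sub>E</sub>−30)</sup>,
with ρ the ERR per Gy at the reference point (attained age 70, exposure age
30), η the attained-age power and γ the per-year age-at-exposure
coefficient. Leukemia (excluding CLL) replaces the γ factor with a
time-since-exposure factor; the default reading is the power law
((a−a<sub>E</sub>)/40)<sup>υ</sup> with υ = −0.81, matching the tabulated
"power −0.81"; the exponential reading e<sup>υ(a−a<sub>E</sub>)/40</sup> is
available behind `leukemia_time_form="exponential"` since the published
formula can be read either way.

The registry (`config/err_params.yaml`) carries the LSS incidence fits per
tissue and sex with their 95% intervals. Conventions:

- Tissues with unreported modifiers (stomach γ; esophagus, pancreas, ovary,
  prostate η and γ) default those modifiers to 0 (no age dependence).
- Lung uses the zero-smoking limit of the generalized multiplicative
  smoking model, represented as a plain solid-form entry; the smoking
  interaction itself is out of scope.
- Esophagus and leukemia share one ρ across sexes (reported differences
  were negligible); breast/ovary are female-only, prostate male-only;
  uterine cancer is excluded (small estimated contribution).
- Thyroid and the remainder ("other") group use the same functional form
  with external-report (BEIR VII style) coefficients from config; the
  thyroid γ = −0.083/yr is a per-year restatement of a per-decade decline.
- The percent-decline-per-decade diagnostic is 100(1 − e<sup>10γ</sup>);
  the 10-year exponent (not e<sup>γ</sup>) is what reproduces the published
  tabulated values.
- Point estimates are never truncated at zero even where the CI spans 0
  (male pancreas); truncation is a Monte-Carlo sampling policy (below).

## Radiation quality and non-targeted effects

Ion effectiveness relative to gamma-rays uses a track-structure scaling

R<sub>QF</sub> = (1 − P)/DDREF + 6.24·(Σ<sub>0</sub>/α<sub>γ</sub>)·P/L,
 P(Z,E) = [1 − e<sup>−Z*²/(κβ²)</sup>]<sup>m</sup>·[1 − e<sup>−E/0.2</sup>],

with L the LET (keV/µm), Z* the Barkas-screened effective charge,
β from relativistic kinematics at kinetic energy E (MeV/u), and DDREF
dividing only the low-LET (penumbra) term. Equivalently, the
targeted-effects pseudo-action cross section per unit fluence is
Σ<sub>TE</sub>/α<sub>γ</sub> = (Σ<sub>0</sub>/α<sub>γ</sub>)P + L(1−P)/6.24
(µm²·Gy; 6.24 converts fluence×LET to Gy at unit density). The bystander
(NTE) term adds η/F with
η = η<sub>0</sub>·x·e<sup>−η₁x</sup>·(1 − e<sup>−F·A<sub>bys</sub></sup>),
x = Z*²/β²: supra-linear at low fluence, saturating over the bystander area
A<sub>bys</sub>, vanishing relative to TE as F → ∞.

**Mixed fields.** Species spectra φ<sub>j</sub>(E) are folded by trapezoid
quadrature on each component's native grid (a 10×-refined grid reproduces
the folds to 1e-3 relative). The NTE fold applies each species' saturating
bracket at its total fluence F<sub>j</sub> and fluence-weights the x-term —
the dimensionally consistent folding of the per-species cross section; the
alternative of placing the spectral density inside the saturation bracket
is not grid-stable and is not used. The hazard scalar passed to the risk
engine is H = Σ<sub>j</sub> ∫ φ<sub>j</sub>(L/6.24)R<sub>QF</sub> dE, which
equals the Σ-fold with the low-LET part divided by DDREF (exactly equal at
DDREF = 1). Solid-cancer and leukemia risks use distinct QF parameter sets
(leukemia RBEs are smaller); a run never mixes TE and NTE modes across
tissues.

**Physics conventions.** LET comes from a Bethe-type parametric stopping
power for water (I = 75 eV, Z/A = 0.5551) scaled by Z*², floored at low
energy where the formula leaves its validity range; it reproduces ~0.22
keV/µm for 1 GeV protons and ~150 keV/µm for 1 GeV/u iron. Both Z* and the
LET model are swappable hooks.

**Numeric defaults** (`config/quality_params.yaml`) are calibration
placeholders, not fitted values: Σ<sub>0</sub>/α<sub>γ</sub> = 700 (solid) /
175 (leukemia) µm²·Gy, κ = 550, m = 3, DDREF = 2 — chosen to give a maximum
quality factor of a few tens near the iron LET peak, the magnitude class of
the published fits. η<sub>0</sub>/α<sub>γ</sub> = 0.004, η₁ = 0.001,
A<sub>bys</sub> = 160 µm² are set once so the NTE variant roughly doubles
the Mars-mission hazard relative to TE, the reported magnitude class for
bystander contributions. Tests exercise formulas, limits and inequalities,
not these numbers.

## Synthetic populations

Real CDC life tables and SEER delay-adjusted rates are not bundled. The
generator is deterministic calibration, not simulation:

- **Life tables**: Gompertz–Makeham hazard μ(a) = c + b·e<sup>θa</sup> with
  fixed c = 5×10⁻⁴ (background/accident floor) and θ = 0.095 (senescent
  doubling ~7.3 y); only b is solved, by bracketing root finding, to hit
  the target life expectancy at birth within 0.1 y. One-parameter
  calibration keeps the inverse problem well-posed; infeasible targets
  (above the c-limited bound of ~97.5 y) raise.
- **Cancer rates**: per-tissue power-law onset curves
  A<sub>T</sub>·max(a − a₀<sub>T</sub>, 0)<sup>k<sub>T</sub></sup> times a
  logistic old-age roll-off centred at 85 (width 6 y in logistic scale at
  80/6 — delay-adjusted incidence flattens and declines above ~85), with a
  bimodal childhood/old-age curve for leukemia. Onsets and powers target
  the familiar median diagnosis ages (breast ~62, prostate ~66, lung ~70).
  Amplitudes are solved in closed form so each tissue contributes its
  configured fraction of the age-adjusted total and the total matches the
  target exactly. Mortality is incidence times a per-tissue
  mortality-to-incidence ratio constrained to (0, 1/1.1], so the
  mortality-consistency correction is a verified no-op on generated tables.
- **Mortality-consistency correction**: wherever background mortality
  exceeds incidence/1.1 (as delay-adjusted incidence can at old ages),
  mortality is capped at incidence/1.1. The rule is idempotent and the cap
  ratio configurable; the implemented direction (incidence 10% above
  mortality) follows the rule's motivation rather than a literal reading
  that would invert it.
- **Age standardisation** uses a documented approximation of the year-2000
  U.S. standard million spread uniformly within 5-year groups (85+ pooled
  over 85–100); the weight vector is an argument everywhere.

What the synthetic populations do *not* capture: true SEER age-specific
curve shapes (only their calibrated summaries), cohort effects, Hispanic
subgroup or regional structure, and the absolute risk scale — lifetime
baseline cancer incidence comes out near 50%, somewhat above U.S.
experience, and together with the placeholder quality-factor scale the
absolute REIC/REID percentages exceed published full-transport analyses by
a factor of a few. Passing tests therefore certify arithmetic, calibration
and comparative structure (rankings, sex and age dependence, TE/NTE
direction), not absolute risk magnitudes. At strong effective doses (e.g.
upper NTE Monte-Carlo draws) the risk sums, which approximate expected
counts, can exceed 100%.

## GCR scenarios

The flux generator is a clearly synthetic stand-in for an environment model
plus transport code: five species groups (H, He, O, Si, Fe) with broad
spectra φ(E) ∝ E/(E+500)<sup>3.3</sup> peaking near 220 MeV/u on a 96-point
log grid (10–5000 MeV/u), scaled per species so configured dose fractions
(H 0.45, He 0.20, O 0.12, Si 0.08, Fe 0.15) sum to a target absorbed-dose
rate within 0.5%. The default 0.4 mGy/day is a representative solar-minimum
dose rate behind 20 g/cm² aluminum; one body-average spectrum stands in for
organ-specific spectra. Shielding itself is not modelled.

Missions are segment lists; each segment is lumped into one acute exposure
at its midpoint age carrying the cumulative fluence (duration × daily flux
× attenuation). The lumping error is bounded in tests: a 1-year exposure as
one event vs. twelve monthly events agrees on REIC within 2%. The Mars
preset is 400 days transit plus 540 days surface with a single
multiplicative surface attenuation of 0.5 (a non-physical knob standing in
for atmospheric shielding; it puts the surface dose rate at 0.2 mGy/day,
consistent with surface measurements).

## Monte-Carlo uncertainty

Parameter PDFs: each tissue's ρ is fitted to its reported central value and
95% interval — normal when the interval is symmetric (or reaches ≤ 0),
lognormal with the central value as median when right-skew exceeds 20%.
Entries without intervals get ±25% normal spreads. DDREF is lognormal
(median 2, GSD 1.3, truncated at 1). The quality-factor scale (lognormal,
σ=0.25), NTE scale (σ=0.7, deliberately wide) and flux scale (σ=0.12) are
placeholder spreads. ρ draws are truncated at 0 — a sampling policy only;
point estimates are never truncated.

Within a trial the DDREF/QF/NTE/flux draws are shared across tissues
(common physics) while ρ draws are independent per tissue (separate
epidemiological fits); both choices are switchable. Sampling uses
counter-based Philox substreams keyed by (master seed, trial index), so
trials are order-independent and bit-reproducible. Intervals are empirical
percentiles (default 2.5/97.5) across ≥100 trials; the point estimate is
always the central-parameter run; non-finite trials are rejected with >1%
rejections an error. On a linear toy model the percentiles match analytic
quantiles within Monte-Carlo error at 10⁵ trials.

## Problem sizes

Default test and example runs use the 101-point age grid, 96-point energy
grids, 8 presets, and 100–1000 Monte-Carlo trials (2000 for the Mars
report); the brute-force oracle runs on 100 randomized small instances.

## Known limitations

No real-data ingestion beyond the CSV formats; no transport or environment
modelling; no smoking interaction beyond the zero-smoking lung limit; no
circulatory or COPD endpoints; no additive/mixture transfer (RR only);
absolute risk scale uncalibrated as discussed above.
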