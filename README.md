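# spacerisk

Lifetime space-radiation cancer risk across populations: **REIC** (risk of
exposure-induced cancer) and **REID** (risk of exposure-induced death) for
galactic-cosmic-ray (GCR) exposures, computed under a relative-risk
transfer model with track-structure radiation quality factors, optional
non-targeted (bystander) effects, and Monte-Carlo uncertainty intervals.

## Who this is for and what it does

Crews on long space missions accumulate doses from a mixed field of protons
and heavy ions. How much lifetime cancer risk that implies depends not only
on the field but on who is exposed: under the relative-risk (RR) transfer
model, radiation multiplies each tissue's *background* cancer rate, and
lifetime risk is limited by competing causes of death — so populations with
different background cancer rates and life expectancies (and females vs
males, and younger vs older crew) carry different risks from the same
exposure. `spacerisk` implements that comparison end to end for
biostatisticians and radiation-protection analysts:

- **Life-table core** — the lifetime risk integral

  REIC = Σ_j ∫ dt λ_I(a_Ej, t, H_T) · S₀(t) · exp(−Σ_k ∫ dz λ_M(a_Ek, z, H_T)),

  with λ_IT = ERR_T(a, a_E) · λ₀IT(a) · H_T, REID likewise with the
  mortality rate λ_MT = (λ₀MT/λ₀IT)·λ_IT, annual steps to age 100, minimum
  latencies of 5 y (solid) and 2 y (leukemia).
- **ERR models** — Life Span Study fits ERR = ρ·D·(a/70)^η·e^{γ(a_E−30)}
  per tissue and sex (time-since-exposure power law for leukemia), shipped
  as an editable registry with 95% CIs.
- **Radiation quality** — R_QF = (1−P)/DDREF + 6.24·Σ₀·P/(α_γ L) with
  P(Z,E) = [1−e^{−Z*²/κβ²}]^m·[1−e^{−E/0.2}], folded over mixed particle
  spectra; a saturating bystander cross-section term for the NTE variant.
- **Synthetic populations** — deterministic Gompertz–Makeham life tables
  and power-law cancer-rate curves calibrated to published life
  expectancies and age-adjusted incidence totals for eight presets
  (API/Black/Hispanic/White × female/male), so the whole pipeline runs
  with no external data.
- **Scenarios & uncertainty** — a parametric GCR flux stand-in calibrated
  to a daily dose rate, 1-year GCR and 940-day Mars mission presets, and
  counter-based Monte-Carlo propagation of parameter PDFs to percentile
  intervals.

## Worked example

```python
import spacerisk as sr

# calibrated synthetic population: life table + tissue-specific rates
life, rates = sr.make_population("white_female")
print(round(sr.life_expectancy(life, 0), 1))          # 81.1 (years, target 81.1)
print(round(sr.age_adjusted_rate(rates.total_incidence()), 1))  # 460.2 per 100,000

# 1-year GCR exposure at age 35, targeted-effects mode
schedule = sr.mission_exposure(sr.gcr_one_year(), 35.0, "TE")
result = sr.compute_risk(schedule, life, rates)
print(round(result.total_reic, 2), round(result.total_reid, 2))  # 27.59 9.29
```

The first two numbers confirm the population hit its calibration targets.
The last line is the total lifetime REIC and REID in percent summed over
tissues — e.g. 27.59 means a 27.59% lifetime probability of a
radiation-attributable cancer diagnosis under this model's conditions.
Comparative structure is the designed use: across the eight presets this
run ranks White females highest and API males lowest, females above males
in every group, and risk decreasing with age at exposure (see
`examples/04_one_year_gcr_comparison.py` and `examples/06_age_scan.py`;
absolute percentages depend on placeholder quality-factor calibration —
see `docs/methods.md`).

From the shell:

```sh
spacerisk synth --out tables/                 # write the calibrated CSVs
spacerisk run --population api_male --scenario mars-940d --mode NTE --mc 1000
spacerisk compare --population white_female   # rank all presets
spacerisk age-scan --population white_female --ages 20,30,40,50,60
spacerisk mars-report --mc 2000 --seed 1
```

Each `examples/*.py` script is a short narrative of one capability and
prints what its numbers mean.

## Layout

```
src/spacerisk/
  population.py   life tables, rate tables, correction, age standardisation
  synthetic.py    calibrated population generator (8 presets)
  err.py          ERR models + registry (config/err_params.yaml)
  quality.py      R_QF, pseudo-action cross sections, mixed-field folding
  scenarios.py    GCR flux stand-in, mission profiles (YAML presets)
  engine.py       REIC/REID lifetime-risk core
  uncertainty.py  parameter PDFs, Monte-Carlo intervals
  reporting.py    run orchestration, comparisons, serialisation
  cli.py          thin command-line wrapper
```
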