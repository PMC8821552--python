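"""Lifetime risk of exposure-induced cancer (REIC) and death (REID).

The instantaneous radiogenic incidence rate for tissue T follows the
relative-risk transfer model

    lambda_IT(aE, a, H_T) = ERR_T(a, aE) * lambda_0IT(a) * H_T,

where ``H_T`` is the gamma-equivalent hazard scalar of the exposure
(quality-scaled dose, Gy) and ``lambda_0IT`` the background incidence in the
population under study.  The mortality rate scales incidence by the
background mortality-to-incidence ratio.  Lifetime risk folds these rates
with the background survival function and the probability of having escaped
radiation cancer death at earlier ages:

    REIC = sum_j  int_{aEj}^{100} dt lambda_Ij(t) S0(t)
                  exp( - sum_k int_{aEk}^{t} dz lambda_Mk(z) ),

and REID likewise with the mortality rate in the outer integrand.  The
integrals are discretized as annual left-Riemann sums on the integer age
grid (the package's piecewise-constant convention), truncated at age 100.
Contributions are zero within the minimum latency after each exposure
(5 years for solid cancers, 2 for leukemia — a hard step, no phase-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .err import MIN_LATENCY, ERRRegistry, err_value
from .population import AGE_MAX, CancerRateTable, LifeTable, per_person_year


@dataclass(frozen=True)
class ExposureEvent:
    """One acute exposure: age and gamma-equivalent hazard scalars.

    ``h_solid`` and ``h_leukemia`` differ because distinct quality-factor
    parameter sets apply to the two endpoint classes; ``absorbed_dose``
    (physical Gy) is carried for provenance only.
    """

    exposure_age: float
    h_solid: float
    h_leukemia: float
    absorbed_dose: float = 0.0

    def __post_init__(self):
        if self.h_solid < 0 or self.h_leukemia < 0:
            raise ValueError("hazard scalars must be >= 0")
        if not (0 <= self.exposure_age <= AGE_MAX):
            raise ValueError("exposure age outside the age grid")

    def hazard_for(self, tissue: str) -> float:
        return self.h_leukemia if tissue == "leukemia" else self.h_solid


@dataclass(frozen=True)
class ExposureSchedule:
    """One or more exposure events, strictly increasing in age."""

    events: tuple
    mode: str = "TE"

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        ages = [e.exposure_age for e in self.events]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("exposure ages must be strictly increasing")
        if self.mode not in ("TE", "NTE"):
            raise ValueError("mode must be 'TE' or 'NTE'")


@dataclass(frozen=True)
class RiskResult:
    """Per-tissue and total lifetime risks, in percent."""

    reic: dict
    reid: dict
    mode: str
    provenance: dict = field(default_factory=dict)
    reic_interval: dict = field(default_factory=dict)
    reid_interval: dict = field(default_factory=dict)

    @property
    def total_reic(self) -> float:
        return self.reic["total"]

    @property
    def total_reid(self) -> float:
        return self.reid["total"]


def _latency(tissue: str) -> float:
    return MIN_LATENCY["leukemia" if tissue == "leukemia" else "solid"]


def radiation_incidence_rate(
    tissue: str,
    sex: str,
    exposure_age: float,
    attained_age,
    hazard_gy: float,
    rates: CancerRateTable,
    registry: ERRRegistry,
):
    """Radiogenic incidence rate per person-year at integer attained age(s).

    Zero below the tissue-class minimum latency.
    """
    params = registry.get(tissue, sex)
    scalar = np.ndim(attained_age) == 0
    a = np.atleast_1d(np.asarray(attained_age, dtype=float))
    lam0 = per_person_year(rates.incidence[tissue])[a.astype(int)]
    out = np.zeros_like(a, dtype=float)
    live = a >= exposure_age + _latency(tissue)
    if np.any(live):
        out[live] = err_value(params, hazard_gy, a[live], exposure_age) * lam0[live]
    return float(out[0]) if scalar else out


def _mortality_ratio(tissue: str, rates: CancerRateTable) -> np.ndarray:
    """Age-specific lambda_0MT / lambda_0IT; zero where both vanish."""
    inc = rates.incidence[tissue]
    mor = rates.mortality[tissue]
    bad = (inc == 0) & (mor > 0)
    if np.any(bad):
        raise ValueError(
            f"{tissue}: background mortality positive where incidence is zero "
            f"(ages {np.flatnonzero(bad)[:5].tolist()}...)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(inc > 0, mor / np.where(inc > 0, inc, 1.0), 0.0)
    return ratio


def radiation_mortality_rate(
    tissue: str,
    sex: str,
    exposure_age: float,
    attained_age,
    hazard_gy: float,
    rates: CancerRateTable,
    registry: ERRRegistry,
):
    """Radiogenic mortality rate: incidence rate scaled by the background
    mortality-to-incidence ratio at the attained age."""
    scalar = np.ndim(attained_age) == 0
    a = np.atleast_1d(np.asarray(attained_age, dtype=float))
    ratio = _mortality_ratio(tissue, rates)[a.astype(int)]
    lam = np.asarray(
        radiation_incidence_rate(tissue, sex, exposure_age, a, hazard_gy, rates, registry)
    )
    out = ratio * lam
    return float(out[0]) if scalar else out


def compute_risk(
    schedule: ExposureSchedule,
    life_table: LifeTable,
    rates: CancerRateTable,
    registry: ERRRegistry | None = None,
    inner_bound: str = "event",
) -> RiskResult:
    """Evaluate REIC and REID (percent) per tissue and in total.

    ``inner_bound`` selects the lower limit of the competing radiation
    mortality integral: ``"event"`` (default) accumulates each event's
    mortality from its own exposure age; ``"outer"`` truncates the inner
    integral at the outer event's exposure age.
    """
    registry = registry or ERRRegistry.default()
    if inner_bound not in ("event", "outer"):
        raise ValueError("inner_bound must be 'event' or 'outer'")
    sex = rates.sex
    registry.validate_against(rates.tissues)
    tissues = [t for t in rates.tissues if registry.has(t, sex)]
    ages = np.arange(AGE_MAX, dtype=float)  # left endpoints 0..99
    s0 = life_table.survival[:AGE_MAX]

    # per-tissue radiogenic rates, per event and summed
    lam_i = {t: np.zeros(AGE_MAX) for t in tissues}
    lam_i_event = []
    for ev in schedule.events:
        per_event = {}
        for t in tissues:
            per_event[t] = np.asarray(
                radiation_incidence_rate(
                    t, sex, ev.exposure_age, ages, ev.hazard_for(t), rates, registry
                )
            )
            lam_i[t] += per_event[t]
        lam_i_event.append(per_event)
    ratio = {t: _mortality_ratio(t, rates)[:AGE_MAX] for t in tissues}
    lam_m = {t: ratio[t] * lam_i[t] for t in tissues}
    lam_m_total = np.sum([lam_m[t] for t in tissues], axis=0)

    # cumulative radiation-mortality integral sum_{z < t}
    cum = np.concatenate(([0.0], np.cumsum(lam_m_total)))  # cum[t] = sum_{z<t}

    reic = {}
    reid = {}
    if inner_bound == "event":
        depletion = np.exp(-cum[:AGE_MAX])
        for t in tissues:
            reic[t] = 100.0 * float(np.sum(lam_i[t] * s0 * depletion))
            reid[t] = 100.0 * float(np.sum(lam_m[t] * s0 * depletion))
    else:
        for t in tissues:
            total_i = 0.0
            total_m = 0.0
            for ev, per_event in zip(schedule.events, lam_i_event):
                start = int(np.floor(ev.exposure_age))
                depl = np.exp(-np.maximum(cum[:AGE_MAX] - cum[start], 0.0))
                total_i += float(np.sum(per_event[t] * s0 * depl))
                total_m += float(np.sum(ratio[t] * per_event[t] * s0 * depl))
            reic[t] = 100.0 * total_i
            reid[t] = 100.0 * total_m

    reic["total"] = float(np.sum([reic[t] for t in tissues]))
    reid["total"] = float(np.sum([reid[t] for t in tissues]))
    for t in tissues:
        if reid[t] > reic[t] + 1e-12:
            raise AssertionError(f"REID exceeds REIC for {t}")
    provenance = {
        "population": rates.population_label,
        "sex": sex,
        "mode": schedule.mode,
        "n_events": len(schedule.events),
        "inner_bound": inner_bound,
        "exposure_ages": [e.exposure_age for e in schedule.events],
        "absorbed_dose_gy": float(sum(e.absorbed_dose for e in schedule.events)),
    }
    return RiskResult(reic=reic, reid=reid, mode=schedule.mode, provenance=provenance)


def reic(schedule, life_table, rates, registry=None, **kw) -> RiskResult:
    """Lifetime risk of exposure-induced cancer (returns the full result)."""
    return compute_risk(schedule, life_table, rates, registry, **kw)


def reid(schedule, life_table, rates, registry=None, **kw) -> RiskResult:
    """Lifetime risk of exposure-induced death (returns the full result)."""
    return compute_risk(schedule, life_table, rates, registry, **kw)
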