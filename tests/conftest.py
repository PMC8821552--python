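import numpy as np
import pytest

import spacerisk as sr

PRESET_NAMES = (
    "api_female",
    "api_male",
    "black_female",
    "black_male",
    "hispanic_female",
    "hispanic_male",
    "white_female",
    "white_male",
)


@pytest.fixture(scope="session")
def populations():
    """Calibrated synthetic (life table, rate table) pairs for all presets."""
    return {name: sr.make_population(name) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def registry():
    return sr.ERRRegistry.default()


@pytest.fixture(scope="session")
def gcr_year_profile():
    return sr.gcr_one_year()


@pytest.fixture(scope="session")
def gcr_year_schedule(gcr_year_profile):
    """1-year GCR exposure starting at age 35, targeted-effects mode."""
    return sr.mission_exposure(gcr_year_profile, 35.0, "TE")


def brute_force_risk(events, life_table, rates, registry, *, mortality=False,
                     with_depletion=True, leukemia_time_form="power"):
    """Independent nested-loop evaluation of the lifetime risk sum.

    Re-implements the ERR forms and the annual left-Riemann double sum from
    scratch (plain Python loops, no calls into the engine) so it can serve
    as an oracle for the vectorised implementation.
    """
    import math

    sex = rates.sex
    s0 = life_table.survival

    def err(tissue, dose, a, a_e):
        p = registry.get(tissue, sex)
        if p.form == "leukemia":
            lat = a - a_e
            if leukemia_time_form == "power":
                tf = (lat / 40.0) ** p.upsilon
            else:
                tf = math.exp(p.upsilon * lat / 40.0)
            return p.rho * dose * (a / 70.0) ** p.eta * tf
        return p.rho * dose * (a / 70.0) ** p.eta * math.exp(p.gamma * (a_e - 30.0))

    def lam_i(tissue, ev, t):
        latency = 2.0 if tissue == "leukemia" else 5.0
        if t < ev.exposure_age + latency:
            return 0.0
        return err(tissue, ev.hazard_for(tissue), float(t), ev.exposure_age) * (
            rates.incidence[tissue][t] / 1e5
        )

    def lam_m(tissue, ev, t):
        inc = rates.incidence[tissue][t]
        if inc == 0.0:
            return 0.0
        return (rates.mortality[tissue][t] / inc) * lam_i(tissue, ev, t)

    tissues = [t for t in rates.tissues if registry.has(t, sex)]
    depletion = []
    for t in range(100):
        inner = 0.0
        if with_depletion:
            for z in range(t):
                for ev in events:
                    for u in tissues:
                        inner += lam_m(u, ev, z)
        depletion.append(math.exp(-inner))
    out = {}
    for tissue in tissues:
        total = 0.0
        for t in range(100):
            outer = sum(
                (lam_m if mortality else lam_i)(tissue, ev, t) for ev in events
            )
            total += outer * s0[t] * depletion[t]
        out[tissue] = 100.0 * total
    out["total"] = sum(out[t] for t in tissues)
    return out


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_risk
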