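import numpy as np
import pytest

import spacerisk as sr
from spacerisk.engine import ExposureEvent, ExposureSchedule
from spacerisk.population import AGES


def flat_rate_table(sex="female", tissue="colon", incidence=100.0, ratio=0.5):
    inc = np.full(101, float(incidence))
    return sr.CancerRateTable(
        "toy", sex, {tissue: inc}, {tissue: inc * ratio}
    )


def single_event(h, age=30.0):
    return ExposureSchedule((ExposureEvent(age, h, h),))


def random_instance(rng, registry):
    """Small random universe: life table, 1-3 tissues, 1-3 events."""
    sex = rng.choice(["female", "male"])
    hazard = rng.uniform(0.0, 0.08, size=101)
    life = sr.LifeTable.from_hazard("rand", sex, hazard)
    pool = [t for t in ("colon", "lung", "stomach", "leukemia", "brain")
            if registry.has(t, sex)]
    chosen = rng.choice(pool, size=rng.integers(1, 4), replace=False)
    inc, mor = {}, {}
    for t in chosen:
        curve = rng.uniform(0.0, 800.0, size=101)
        inc[t] = curve
        mor[t] = curve * rng.uniform(0.1, 1 / 1.1)
    rates = sr.CancerRateTable("rand", sex, inc, mor)
    ages = np.sort(rng.uniform(5.0, 80.0, size=rng.integers(1, 4)))
    ages += np.arange(len(ages)) * 0.5  # strictly increasing
    events = tuple(
        ExposureEvent(float(a), float(rng.uniform(0, 2.0)), float(rng.uniform(0, 2.0)))
        for a in ages
    )
    return ExposureSchedule(events), life, rates


class TestRadiationRates:
    def test_zero_hazard_gives_zero_rate_at_all_ages(self, registry):
        rates = flat_rate_table()
        out = sr.radiation_incidence_rate(
            "colon", "female", 30.0, AGES[:-1].astype(float), 0.0, rates, registry
        )
        assert np.all(out == 0.0)

    def test_solid_latency_gate(self, registry):
        rates = flat_rate_table()
        inside = sr.radiation_incidence_rate("colon", "female", 30.0, 34.9, 1.0, rates, registry)
        outside = sr.radiation_incidence_rate("colon", "female", 30.0, 35.0, 1.0, rates, registry)
        assert inside == 0.0
        assert outside > 0.0

    def test_leukemia_latency_is_two_years(self, registry):
        rates = flat_rate_table(tissue="leukemia")
        assert sr.radiation_incidence_rate("leukemia", "female", 30.0, 31.9, 1.0, rates, registry) == 0.0
        assert sr.radiation_incidence_rate("leukemia", "female", 30.0, 32.0, 1.0, rates, registry) > 0.0

    def test_all_solid_reference_hand_arithmetic(self, registry):
        # flat background 100/1e5, female all-solid rho=0.6, H=1 Gy,
        # a=70, aE=30: rate = 0.6 * 100/1e5 = 6.0e-4
        inc = np.full(101, 100.0)
        rates = sr.CancerRateTable("toy", "female", {"all_solid": inc},
                                   {"all_solid": inc * 0.5})
        rate = sr.radiation_incidence_rate("all_solid", "female", 30.0, 70.0, 1.0,
                                           rates, registry)
        assert rate == pytest.approx(6.0e-4, rel=1e-12)
        mrate = sr.radiation_mortality_rate("all_solid", "female", 30.0, 70.0, 1.0,
                                            rates, registry)
        assert mrate == pytest.approx(3.0e-4, rel=1e-12)

    def test_mortality_rate_equals_incidence_when_ratio_one(self, registry):
        rates = flat_rate_table(ratio=1.0)
        i = sr.radiation_incidence_rate("colon", "female", 30.0, 60.0, 1.0, rates, registry)
        m = sr.radiation_mortality_rate("colon", "female", 30.0, 60.0, 1.0, rates, registry)
        assert m == pytest.approx(i)

    def test_zero_background_mortality_gives_zero(self, registry):
        rates = flat_rate_table(ratio=0.0)
        assert sr.radiation_mortality_rate("colon", "female", 30.0, 60.0, 1.0,
                                           rates, registry) == 0.0

    def test_positive_mortality_with_zero_incidence_errors(self, registry):
        inc = np.zeros(101)
        mor = np.full(101, 5.0)
        with pytest.raises(ValueError, match="incidence is zero"):
            rates = sr.CancerRateTable("bad", "female", {"colon": inc}, {"colon": mor})
            sr.radiation_mortality_rate("colon", "female", 30.0, 60.0, 1.0,
                                        rates, sr.ERRRegistry.default())

    def test_unknown_tissue_errors(self, registry):
        rates = flat_rate_table()
        with pytest.raises(KeyError):
            sr.radiation_incidence_rate("spleen", "female", 30.0, 60.0, 1.0, rates, registry)


class TestLifetimeRisk:
    def test_null_exposure_gives_exact_zero(self, populations, registry):
        table, rates = populations["api_male"]
        res = sr.compute_risk(single_event(0.0), table, rates, registry)
        assert res.total_reic == 0.0
        assert res.total_reid == 0.0

    def test_small_dose_linearity(self, populations, registry):
        table, rates = populations["white_female"]
        eps = 1e-3  # 1 mGy-equivalent
        r1 = sr.compute_risk(single_event(eps), table, rates, registry)
        r2 = sr.compute_risk(single_event(2 * eps), table, rates, registry)
        assert r2.total_reic / r1.total_reic == pytest.approx(2.0, rel=1e-3)

    def test_three_age_toy_universe_matches_enumeration(self, registry, brute_force):
        # tiny hand-set universe, exhaustively enumerable
        hazard = np.zeros(101)
        hazard[:3] = [0.01, 0.02, 0.03]
        life = sr.LifeTable.from_hazard("toy", "male", hazard)
        inc = np.zeros(101)
        inc[:80] = 300.0
        rates = sr.CancerRateTable("toy", "male", {"colon": inc}, {"colon": inc * 0.4})
        sched = single_event(0.8, age=10.0)
        expected = brute_force(sched.events, life, rates, registry)
        got = sr.compute_risk(sched, life, rates, registry)
        assert got.reic["colon"] == pytest.approx(expected["colon"], rel=1e-12)

    def test_engine_matches_brute_force_on_random_instances(self, registry, brute_force):
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            sched, life, rates = random_instance(rng, registry)
            got = sr.compute_risk(sched, life, rates, registry)
            exp_i = brute_force(sched.events, life, rates, registry)
            exp_m = brute_force(sched.events, life, rates, registry, mortality=True)
            for t in rates.tissues:
                assert got.reic[t] == pytest.approx(exp_i[t], rel=1e-10, abs=1e-14)
                assert got.reid[t] == pytest.approx(exp_m[t], rel=1e-10, abs=1e-14)

    def test_reid_below_reic_for_every_tissue(self, populations, gcr_year_schedule, registry):
        for table, rates in populations.values():
            res = sr.compute_risk(gcr_year_schedule, table, rates, registry)
            for t in rates.tissues:
                assert 0.0 <= res.reid[t] <= res.reic[t]

    def test_totals_are_sums_over_tissues(self, populations, gcr_year_schedule, registry):
        table, rates = populations["hispanic_male"]
        res = sr.compute_risk(gcr_year_schedule, table, rates, registry)
        assert res.total_reic == pytest.approx(
            sum(v for k, v in res.reic.items() if k != "total"), abs=1e-9
        )

    def test_reic_monotone_in_hazard(self, populations, registry):
        table, rates = populations["black_female"]
        vals = [
            sr.compute_risk(single_event(h), table, rates, registry).total_reic
            for h in (0.1, 0.2, 0.5, 1.0)
        ]
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]

    def test_longer_life_expectancy_raises_reic_at_equal_rates(self, populations, registry):
        # the Black/White male mechanism: same background rates, different
        # survival; the longer-lived table accrues more lifetime risk
        _, rates = populations["white_male"]
        short = sr.make_life_table(
            sr.PopulationSpec("white", "male", 71.3, 520.4)
        )
        long = sr.make_life_table(
            sr.PopulationSpec("white", "male", 81.0, 520.4)
        )
        sched = single_event(0.5, age=35.0)
        r_short = sr.compute_risk(sched, short, rates, registry)
        r_long = sr.compute_risk(sched, long, rates, registry)
        assert r_long.total_reic > r_short.total_reic

    def test_depletion_term_small_at_low_dose_but_grows_with_dose(
        self, registry, brute_force
    ):
        # the competing-radiation-mortality exponential is a sub-percent
        # correction at sub-0.1-Gy-equivalent scales but bites at multi-Gy;
        # dropping it can only increase REIC
        hazard = np.full(101, 0.01)
        life = sr.LifeTable.from_hazard("toy", "female", hazard)
        inc = np.full(101, 400.0)
        rates = sr.CancerRateTable("toy", "female", {"lung": inc}, {"lung": inc * 0.55})
        rels = []
        for h in (0.05, 2.0, 20.0):
            sched = single_event(h, age=35.0)
            with_dep = brute_force(sched.events, life, rates, registry)["lung"]
            without = brute_force(sched.events, life, rates, registry,
                                  with_depletion=False)["lung"]
            rel = (without - with_dep) / with_dep
            assert rel >= 0.0  # dropping the exponential can only raise REIC
            rels.append(rel)
        assert rels[0] < 0.005
        assert rels[1] > 0.01
        assert rels == sorted(rels)

    def test_inner_bound_variants_agree_for_single_event(self, populations, registry):
        table, rates = populations["api_female"]
        sched = single_event(0.3, age=40.0)
        a = sr.compute_risk(sched, table, rates, registry, inner_bound="event")
        b = sr.compute_risk(sched, table, rates, registry, inner_bound="outer")
        assert a.total_reic == pytest.approx(b.total_reic, rel=1e-12)

    def test_exposure_ages_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ExposureSchedule((ExposureEvent(40.0, 1.0, 1.0), ExposureEvent(35.0, 1.0, 1.0)))
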