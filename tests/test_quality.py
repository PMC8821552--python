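import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spacerisk as sr
from spacerisk.quality import (
    AMU_MEV,
    FLUENCE_LET_TO_GY,
    beta_from_energy,
    default_nte_params,
    default_qf_params,
    nte_eta,
)


def independent_x(z, e_mev_u):
    """Re-derivation of Z*^2/beta^2 from the two defining formulas."""
    gamma = 1.0 + e_mev_u / AMU_MEV
    beta = math.sqrt(1.0 - gamma**-2)
    zstar = z * (1.0 - math.exp(-125.0 * beta * z ** (-2.0 / 3.0)))
    return zstar**2 / beta**2


def monoenergetic(z, e0, fluence, width=1e-3):
    """Delta-like narrow triangular bin carrying a known total fluence."""
    grid = np.array([e0 - width, e0, e0 + width])
    phi = np.array([0.0, fluence / width, 0.0])
    return sr.ParticleFlux((sr.FluxComponent(z, grid, phi),))


class TestKinematicsAndCharge:
    def test_ultrarelativistic_proton_limit(self):
        # beta -> 1, Z* -> 1, so x -> 1
        assert sr.effective_charge_sq_over_beta_sq(1, 5e6) == pytest.approx(1.0, rel=1e-3)

    def test_low_speed_screening_kills_effective_charge(self):
        from spacerisk.quality import effective_charge

        assert effective_charge(26, 1e-6) == pytest.approx(0.0, abs=0.05)

    def test_iron_1000_mev_matches_independent_oracle(self):
        assert sr.effective_charge_sq_over_beta_sq(26, 1000.0) == pytest.approx(
            independent_x(26, 1000.0), rel=1e-12
        )

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            beta_from_energy(0.0)

    def test_let_magnitudes_are_physical(self):
        # ~0.2 keV/um for 1 GeV protons, ~150 keV/um for 1 GeV/u iron
        assert sr.let_water(1, 1000.0) == pytest.approx(0.22, abs=0.05)
        assert sr.let_water(26, 1000.0) == pytest.approx(150.0, rel=0.2)


class TestPFunction:
    def test_vanishes_at_zero_energy(self):
        qf = default_qf_params("solid")
        assert sr.p_function(26, 1e-4, qf) == pytest.approx(0.0, abs=1e-3)

    def test_saturates_to_one(self):
        qf = default_qf_params("solid")
        # huge x/kappa and E >> 0.2: both brackets -> 1
        assert sr.p_function(26, 100.0, qf) == pytest.approx(
            (1 - math.exp(-independent_x(26, 100.0) / qf.kappa)) ** qf.m, rel=1e-9
        )

    def test_midrange_matches_direct_formula(self):
        qf = default_qf_params("solid")
        x = independent_x(14, 600.0)
        expected = (1 - math.exp(-x / qf.kappa)) ** qf.m * (1 - math.exp(-600.0 / 0.2))
        assert sr.p_function(14, 600.0, qf) == pytest.approx(expected, rel=1e-12)

    def test_bounded_and_monotone_in_charge(self):
        qf = default_qf_params("solid")
        vals = [sr.p_function(z, 600.0, qf) for z in (1, 2, 8, 14, 26)]
        assert all(0 <= v <= 1 for v in vals)
        assert vals == sorted(vals)


class TestRqfAndCrossSections:
    def test_low_let_limit_is_inverse_ddref(self):
        # high-energy proton: P ~ 1e-8, so R_QF -> 1/DDREF
        qf = default_qf_params("solid")
        assert sr.r_qf(1, 4000.0, qf) == pytest.approx(1.0 / qf.ddref, rel=1e-3)

    def test_rqf_consistent_with_sigma_te(self):
        # algebraic identity: R_QF = 6.24*Sigma_TE/L with the low-LET part
        # divided by DDREF
        qf = default_qf_params("solid")
        z, e = 26, 600.0
        p = sr.p_function(z, e, qf)
        let = sr.let_water(z, e)
        sigma = sr.sigma_te(z, e, qf)
        high = qf.sigma0_over_alpha * p
        low = let * (1 - p) / FLUENCE_LET_TO_GY
        assert sigma == pytest.approx(high + low, rel=1e-12)
        expected_rqf = FLUENCE_LET_TO_GY * high / let + (1 - p) / qf.ddref
        assert sr.r_qf(z, e, qf) == pytest.approx(expected_rqf, rel=1e-12)

    def test_sigma_nte_reduces_to_te_when_eta0_zero(self):
        qf = default_qf_params("solid")
        nte = sr.NTEParams(0.0, 0.001, 160.0)
        assert sr.sigma_nte(26, 600.0, 0.01, qf, nte) == pytest.approx(
            sr.sigma_te(26, 600.0, qf)
        )

    def test_sigma_nte_exceeds_te_and_saturates_at_high_fluence(self):
        qf = default_qf_params("solid")
        nte = default_nte_params()
        te = sr.sigma_te(26, 600.0, qf)
        assert sr.sigma_nte(26, 600.0, 1e-3, qf, nte) > te
        assert sr.sigma_nte(26, 600.0, 1e6, qf, nte) == pytest.approx(te, rel=1e-5)

    def test_sigma_nte_matches_direct_formula(self):
        qf = default_qf_params("solid")
        nte = default_nte_params()
        z, e, f = 14, 250.0, 0.02
        x = independent_x(z, e)
        eta = nte.eta0_over_alpha * x * math.exp(-nte.eta1 * x) * (
            1 - math.exp(-f * nte.a_bys)
        )
        assert nte_eta(z, e, f, nte) == pytest.approx(eta, rel=1e-12)
        assert sr.sigma_nte(z, e, f, qf, nte) == pytest.approx(
            sr.sigma_te(z, e, qf) + eta / f, rel=1e-12
        )

    def test_nonpositive_fluence_rejected(self):
        qf = default_qf_params("solid")
        with pytest.raises(ValueError):
            sr.sigma_nte(26, 600.0, 0.0, qf, default_nte_params())


class TestMixedFieldFolding:
    def test_monoenergetic_fold_is_pointwise_product(self):
        qf = default_qf_params("solid")
        flux = monoenergetic(26, 600.0, fluence=0.005)
        expected = sr.sigma_te(26, 600.0, qf) * 0.005
        assert sr.fold_te(flux, qf) == pytest.approx(expected, rel=1e-4)

    def test_two_species_fold_matches_fine_grid_quadrature(self):
        qf = default_qf_params("solid")
        flux = sr.make_gcr_flux(0.4, species_mix=(("H", 1, 0.6), ("Fe", 26, 0.4)))
        total = 0.0
        for c in flux.components:
            fine = np.geomspace(c.energy[0], c.energy[-1], len(c.energy) * 10)
            phi = np.interp(fine, c.energy, c.phi)
            total += np.trapezoid(phi * sr.sigma_te(c.z, fine, qf), fine)
        assert sr.fold_te(flux, qf) == pytest.approx(total, rel=1e-3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nte_fold_never_below_te_fold(self, seed):
        rng = np.random.default_rng(seed)
        qf = default_qf_params("solid")
        nte = default_nte_params()
        comps = []
        for z in rng.choice([1, 2, 8, 14, 26], size=rng.integers(1, 4), replace=False):
            e = np.sort(rng.uniform(10, 3000, size=12))
            e += np.arange(12) * 1e-6  # strictly increasing
            comps.append(sr.FluxComponent(int(z), e, rng.uniform(0, 1e-3, size=12)))
        flux = sr.ParticleFlux(tuple(comps))
        assert sr.fold_nte(flux, qf, nte) >= sr.fold_te(flux, qf) - 1e-15

    def test_te_fold_linear_in_fluence_scale(self):
        qf = default_qf_params("solid")
        flux = sr.make_gcr_flux(0.4)
        assert sr.fold_te(flux.scaled(3.0), qf) == pytest.approx(
            3.0 * sr.fold_te(flux, qf), rel=1e-12
        )

    def test_nte_hazard_per_fluence_non_increasing(self):
        qf = default_qf_params("solid")
        nte = default_nte_params()
        flux = sr.make_gcr_flux(0.4)
        scales = [0.5, 1.0, 4.0, 20.0]
        per_unit = [
            sr.gamma_equivalent_dose(flux.scaled(c), qf, "NTE", nte) / c for c in scales
        ]
        assert all(b <= a + 1e-12 for a, b in zip(per_unit, per_unit[1:]))

    def test_empty_flux_warns_and_returns_zero(self):
        qf = default_qf_params("solid")
        with pytest.warns(UserWarning, match="empty flux"):
            assert sr.fold_te(sr.ParticleFlux(()), qf) == 0.0


class TestGammaEquivalentDose:
    def test_dose_from_flux_matches_hand_computation(self):
        # one proton component: D = F * L / 6.24 with L evaluated by an
        # independently coded Bethe expression
        e0, fluence = 600.0, 0.01
        flux = monoenergetic(1, e0, fluence)
        gamma = 1.0 + e0 / AMU_MEV
        beta2 = 1.0 - gamma**-2
        zstar = 1.0 * (1.0 - math.exp(-125.0 * math.sqrt(beta2)))
        log_term = math.log(2 * 0.510999 * beta2 * gamma**2 / 75e-6)
        let = 0.307075 * 0.5551 * zstar**2 / beta2 * (log_term - beta2) * 0.1
        assert flux.absorbed_dose() == pytest.approx(fluence * let / 6.24, rel=1e-4)

    def test_low_let_flux_reduces_to_dose_over_ddref(self):
        qf = default_qf_params("solid")
        flux = make_high_energy_protons()
        h = sr.gamma_equivalent_dose(flux, qf, "TE")
        assert h == pytest.approx(flux.absorbed_dose() / qf.ddref, rel=1e-3)

    def test_unit_ddref_low_let_equals_physical_dose(self):
        qf = sr.QFParams(700.0, 550.0, 3, 1.0, "solid")
        flux = make_high_energy_protons()
        assert sr.gamma_equivalent_dose(flux, qf, "TE") == pytest.approx(
            flux.absorbed_dose(), rel=1e-3
        )

    def test_te_hazard_strictly_proportional_to_fluence(self):
        qf = default_qf_params("solid")
        flux = sr.make_gcr_flux(0.4)
        h1 = sr.gamma_equivalent_dose(flux, qf, "TE")
        h2 = sr.gamma_equivalent_dose(flux.scaled(2.0), qf, "TE")
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_rqf_and_sigma_formulations_agree(self):
        # at DDREF=1 the R_QF fold equals the cross-section fold exactly
        qf = sr.QFParams(700.0, 550.0, 3, 1.0, "solid")
        flux = sr.make_gcr_flux(0.4)
        assert sr.gamma_equivalent_dose(flux, qf, "TE") == pytest.approx(
            sr.fold_te(flux, qf), rel=1e-10
        )


def make_high_energy_protons():
    e = np.geomspace(2000.0, 5000.0, 40)
    phi = np.full_like(e, 1e-5)
    return sr.ParticleFlux((sr.FluxComponent(1, e, phi),))
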