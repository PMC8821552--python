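"""Radiation-quality scaling for charged-particle fields.

The effectiveness of an ion of charge ``Z`` and kinetic energy ``E`` (MeV per
nucleon) relative to gamma-rays is described by a track-structure-motivated
scaling factor

    R_QF = (1 - P) / DDREF + 6.24 * (Sigma0/alpha_gamma) * P / L,

where ``L`` is the LET in keV/um, ``P(Z, E)`` interpolates between the
low-LET ("penumbra") and track-core regimes, and DDREF divides only the
low-LET term.  Equivalently the model defines a pseudo-action cross section
(effectiveness per unit fluence, um^2)

    Sigma_TE / alpha_gamma = (Sigma0/alpha_gamma) * P + L * (1 - P) / 6.24,

with RBE = 6.24 * Sigma / (L * alpha_gamma); only ratios to the gamma-ray
linear slope alpha_gamma ever enter, so all cross sections here carry units
of um^2 * Gy.  A non-targeted (bystander) term that saturates with fluence
can be added on top of the targeted term.

The factor 6.24 converts fluence x LET to dose: 1 Gy = 6.24 keV/um per
um^-2 of fluence in unit-density tissue.

Stopping powers use a Bethe-type parametric formula for water with
Barkas-screened effective charge; both are standard external physics
conventions, swappable via the ``let_fn`` hook on :class:`ParticleFlux`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

#: keV/um per (Gy * um^-2): dose = fluence * LET / 6.24.
FLUENCE_LET_TO_GY = 6.24

#: Atomic mass unit rest energy, MeV (kinetic energies are per nucleon).
AMU_MEV = 931.494

_ELECTRON_MASS_MEV = 0.510999
_WATER_Z_OVER_A = 0.5551
_WATER_I_MEV = 75e-6
_BETHE_K = 0.307075  # MeV cm^2 / mol


def beta_from_energy(energy_mev_u):
    """Relativistic speed (v/c) at kinetic energy per nucleon E (MeV/u)."""
    e = np.asarray(energy_mev_u, dtype=float)
    if np.any(e <= 0):
        raise ValueError("kinetic energy must be > 0")
    gamma = 1.0 + e / AMU_MEV
    out = np.sqrt(1.0 - 1.0 / gamma**2)
    return out if out.ndim else float(out)


def effective_charge(z: int, energy_mev_u):
    """Barkas effective charge Z* = Z [1 - exp(-125 beta Z^{-2/3})]."""
    if z < 1:
        raise ValueError("charge number must be >= 1")
    beta = beta_from_energy(energy_mev_u)
    return z * (1.0 - np.exp(-125.0 * np.asarray(beta) * z ** (-2.0 / 3.0)))


def effective_charge_sq_over_beta_sq(z: int, energy_mev_u):
    """x = Z*^2 / beta^2, the track-structure scaling variable."""
    beta = np.asarray(beta_from_energy(energy_mev_u))
    zstar = effective_charge(z, energy_mev_u)
    out = zstar**2 / beta**2
    return out if out.ndim else float(out)


def let_water(z: int, energy_mev_u):
    """LET in water, keV/um, from a Bethe-type parametric stopping power.

    Scales a proton Bethe stopping power by Z*^2; the logarithmic term is
    floored so the expression stays positive at low energies (where the
    Bethe formula is outside its validity range anyway).
    """
    e = np.asarray(energy_mev_u, dtype=float)
    beta = np.asarray(beta_from_energy(e))
    gamma = 1.0 + e / AMU_MEV
    zstar = np.asarray(effective_charge(z, e))
    log_term = np.log(2.0 * _ELECTRON_MASS_MEV * beta**2 * gamma**2 / _WATER_I_MEV)
    stopping_number = np.maximum(log_term - beta**2, 0.2)
    s = _BETHE_K * _WATER_Z_OVER_A * zstar**2 / beta**2 * stopping_number  # MeV cm^2/g
    out = s * 0.1  # unit density: MeV/cm -> keV/um
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class QFParams:
    """Quality-factor parameters for one endpoint class (solid or leukemia)."""

    sigma0_over_alpha: float  # um^2 * Gy
    kappa: float
    m: float
    ddref: float
    endpoint_class: str = "solid"

    def __post_init__(self):
        if min(self.sigma0_over_alpha, self.kappa, self.m, self.ddref) <= 0:
            raise ValueError("QF parameters must be positive")
        if self.m < 1:
            raise ValueError("saturation exponent m must be >= 1")


@dataclass(frozen=True)
class NTEParams:
    """Non-targeted (bystander) effect parameters."""

    eta0_over_alpha: float  # um^2 * Gy per unit x
    eta1: float             # per unit x
    a_bys: float            # bystander area, um^2

    def __post_init__(self):
        if self.eta0_over_alpha < 0 or self.eta1 < 0:
            raise ValueError("NTE parameters must be >= 0")
        if self.a_bys <= 0:
            raise ValueError("bystander area must be > 0")


def load_quality_config() -> dict:
    text = resources.files("spacerisk.config").joinpath("quality_params.yaml").read_text()
    return yaml.safe_load(text)


def default_qf_params(endpoint_class: str = "solid") -> QFParams:
    cfg = load_quality_config()[endpoint_class]
    return QFParams(
        sigma0_over_alpha=cfg["sigma0_over_alpha"],
        kappa=cfg["kappa"],
        m=cfg["m"],
        ddref=cfg["ddref"],
        endpoint_class=endpoint_class,
    )


def default_nte_params() -> NTEParams:
    cfg = load_quality_config()["nte"]
    return NTEParams(cfg["eta0_over_alpha"], cfg["eta1"], cfg["a_bys"])


# ---------------------------------------------------------------------------
# Point functions
# ---------------------------------------------------------------------------


def p_function(z: int, energy_mev_u, params: QFParams):
    """P(Z,E) = [1 - exp(-Z*^2/(kappa beta^2))]^m [1 - exp(-E/0.2)] in [0,1]."""
    e = np.asarray(energy_mev_u, dtype=float)
    x = np.asarray(effective_charge_sq_over_beta_sq(z, e))
    out = (1.0 - np.exp(-x / params.kappa)) ** params.m * (1.0 - np.exp(-e / 0.2))
    return out if out.ndim else float(out)


def r_qf(z: int, energy_mev_u, params: QFParams, let_fn=let_water):
    """Gamma-ray-relative scaling factor R_QF = (1-P)/DDREF + 6.24 Sigma0 P/(alpha L)."""
    p = np.asarray(p_function(z, energy_mev_u, params))
    let = np.asarray(let_fn(z, energy_mev_u), dtype=float)
    if np.any(let <= 0):
        raise ValueError("LET must be > 0 for the track-core term")
    out = (1.0 - p) / params.ddref + FLUENCE_LET_TO_GY * params.sigma0_over_alpha * p / let
    return out if out.ndim else float(out)


def sigma_te(z: int, energy_mev_u, params: QFParams, let_fn=let_water):
    """Targeted-effect pseudo-action cross section over alpha_gamma (um^2 Gy)."""
    p = np.asarray(p_function(z, energy_mev_u, params))
    let = np.asarray(let_fn(z, energy_mev_u), dtype=float)
    out = params.sigma0_over_alpha * p + let * (1.0 - p) / FLUENCE_LET_TO_GY
    return out if out.ndim else float(out)


def nte_eta(z: int, energy_mev_u, fluence_per_um2, nte: NTEParams):
    """Bystander term eta/alpha_gamma = eta0 x e^{-eta1 x} [1 - e^{-F A_bys}]."""
    x = np.asarray(effective_charge_sq_over_beta_sq(z, energy_mev_u))
    f = np.asarray(fluence_per_um2, dtype=float)
    out = nte.eta0_over_alpha * x * np.exp(-nte.eta1 * x) * (-np.expm1(-f * nte.a_bys))
    return out if out.ndim else float(out)


def sigma_nte(
    z: int, energy_mev_u, fluence_per_um2, params: QFParams, nte: NTEParams, let_fn=let_water
):
    """Total (targeted + bystander) cross section over alpha_gamma.

    ``fluence_per_um2`` is the species fluence F; the bystander contribution
    eta/F vanishes as F grows (saturation), so sigma_nte >= sigma_te always
    and approaches it at high fluence.
    """
    f = np.asarray(fluence_per_um2, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fluence must be > 0 for the NTE cross section")
    out = np.asarray(sigma_te(z, energy_mev_u, params, let_fn)) + np.asarray(
        nte_eta(z, energy_mev_u, f, nte)
    ) / f
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Mixed fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxComponent:
    """One ion species: charge number, energy grid (MeV/u, strictly
    increasing) and differential fluence spectrum (um^-2 per MeV/u)."""

    z: int
    energy: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        energy = np.asarray(self.energy, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "energy", energy)
        object.__setattr__(self, "phi", phi)
        if energy.ndim != 1 or energy.shape != phi.shape:
            raise ValueError("energy grid and spectrum must be 1-D and matched")
        if np.any(np.diff(energy) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(phi < 0):
            raise ValueError("fluence spectrum must be >= 0")

    @property
    def fluence(self) -> float:
        """Total fluence, um^-2 (trapezoid over the energy grid)."""
        return float(np.trapezoid(self.phi, self.energy))


@dataclass(frozen=True)
class ParticleFlux:
    """Mixed charged-particle field as a list of species spectra."""

    components: tuple
    let_fn: object = field(default=let_water, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def total_fluence(self) -> float:
        return sum(c.fluence for c in self.components)

    def scaled(self, factor: float) -> "ParticleFlux":
        """Flux with every spectrum multiplied by ``factor``."""
        comps = tuple(replace(c, phi=c.phi * factor) for c in self.components)
        return ParticleFlux(comps, self.let_fn)

    def absorbed_dose(self) -> float:
        """Physical absorbed dose in Gy: D = sum_j int phi_j L / 6.24 dE."""
        total = 0.0
        for c in self.components:
            let = np.asarray(self.let_fn(c.z, c.energy), dtype=float)
            total += float(np.trapezoid(c.phi * let, c.energy)) / FLUENCE_LET_TO_GY
        return total


def fold_te(flux: ParticleFlux, params: QFParams) -> float:
    """Mixed-field targeted fold (Sigma F)_TE = sum_j int phi_j Sigma_TE dE.

    Units: um^2 Gy x um^-2 = Gy (gamma-equivalent scale, since cross sections
    are carried as Sigma/alpha_gamma).
    """
    if not flux.components:
        warnings.warn("empty flux: fold is 0", stacklevel=2)
        return 0.0
    total = 0.0
    for c in flux.components:
        sig = np.asarray(sigma_te(c.z, c.energy, params, flux.let_fn))
        total += float(np.trapezoid(c.phi * sig, c.energy))
    return total


def fold_nte(flux: ParticleFlux, params: QFParams, nte: NTEParams) -> float:
    """Mixed-field fold with the non-targeted term added.

    Folds the per-species cross section of the bystander model directly:
    each species j with total fluence F_j contributes

        int phi_j Sigma_TE dE
        + eta0 [1 - e^{-A_bys F_j}] / F_j * int phi_j x e^{-eta1 x} dE,

    i.e. the fluence-weighted bystander term with its saturating bracket
    evaluated at the species fluence.  The addition is >= 0 termwise, so
    (Sigma F)_NTE >= (Sigma F)_TE for every flux, and the bystander part
    grows sublinearly with fluence scale (saturation).
    """
    if not flux.components:
        warnings.warn("empty flux: fold is 0", stacklevel=2)
        return 0.0
    total = fold_te(flux, params)
    for c in flux.components:
        f_j = c.fluence
        if f_j <= 0:
            continue
        x = np.asarray(effective_charge_sq_over_beta_sq(c.z, c.energy))
        weighted = float(np.trapezoid(c.phi * x * np.exp(-nte.eta1 * x), c.energy))
        total += nte.eta0_over_alpha * (-np.expm1(-nte.a_bys * f_j)) / f_j * weighted
    return total


def gamma_equivalent_dose(
    flux: ParticleFlux, params: QFParams, mode: str = "TE", nte: NTEParams | None = None
) -> float:
    """Gamma-equivalent hazard scalar H (Gy) for a mixed field.

    H = sum_j int phi_j (L/6.24) R_QF dE, which equals the targeted fold with
    the low-LET term divided by DDREF.  This is the quantity that multiplies
    the ERR-per-Gy in the risk engine.  In NTE mode the bystander fold term
    (DDREF-free, high-LET physics) is added.
    """
    if mode not in ("TE", "NTE"):
        raise ValueError(f"mode must be 'TE' or 'NTE', got {mode!r}")
    if not flux.components:
        warnings.warn("empty flux: dose is 0", stacklevel=2)
        return 0.0
    total = 0.0
    for c in flux.components:
        let = np.asarray(flux.let_fn(c.z, c.energy), dtype=float)
        rq = np.asarray(r_qf(c.z, c.energy, params, flux.let_fn))
        total += float(np.trapezoid(c.phi * let / FLUENCE_LET_TO_GY * rq, c.energy))
    if mode == "NTE":
        if nte is None:
            raise ValueError("NTE mode requires NTEParams")
        total += fold_nte(flux, params, nte) - fold_te(flux, params)
    return total
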