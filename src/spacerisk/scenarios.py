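"""GCR-like flux fixtures and mission exposure schedules.

The real pipeline obtains particle spectra behind spacecraft shielding from
an environment model plus a transport code.  This module is a clearly
synthetic parametric stand-in: five representative species groups (H, He,
C/O, Si, Fe) with broad energy spectra peaking at a few hundred MeV/u,
globally scaled so the physical absorbed-dose rate matches a requested
target.  All flux fixtures are nominally "behind 20 g/cm^2 aluminum" by
construction — shielding itself is not modelled.

Mission profiles chain segments (e.g. Mars transit and surface stay); each
segment is lumped into a single acute exposure at its midpoint age, with a
configurable attenuation factor standing in for the Mars atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quality
from .engine import ExposureEvent, ExposureSchedule
from .population import AGE_MAX
from .quality import FluxComponent, ParticleFlux

#: Default species groups: (label, charge number, fraction of absorbed dose).
#: Dose fractions are a coarse GCR split behind nominal shielding: protons
#: carry most of the dose, the HZE groups the rest.
DEFAULT_SPECIES_MIX = (
    ("H", 1, 0.45),
    ("He", 2, 0.20),
    ("O", 8, 0.12),
    ("Si", 14, 0.08),
    ("Fe", 26, 0.15),
)

#: Reference GCR absorbed dose rate near solar minimum behind 20 g/cm^2
#: aluminum, mGy/day.
SOLAR_MIN_DOSE_RATE = 0.4

#: Default Mars-surface flux attenuation (atmosphere + planetary shadowing).
MARS_SURFACE_ATTENUATION = 0.5

_ENERGY_GRID = np.geomspace(10.0, 5000.0, 96)  # MeV/u


def _spectrum_shape(energy: np.ndarray) -> np.ndarray:
    """Broad GCR-like spectral shape, peaking near ~220 MeV/u."""
    return energy / (energy + 500.0) ** 3.3


def make_gcr_flux(
    dose_rate_target: float = SOLAR_MIN_DOSE_RATE,
    species_mix=DEFAULT_SPECIES_MIX,
    energy_grid: np.ndarray | None = None,
) -> ParticleFlux:
    """Deterministic synthetic GCR flux scaled to a daily absorbed-dose rate.

    Parameters
    ----------
    dose_rate_target : float
        Physical absorbed-dose rate in mGy/day the returned daily fluence
        must reproduce (via ``ParticleFlux.absorbed_dose``) within 0.5%.
    species_mix : iterable of (label, Z, dose_fraction)
        Fractions must sum to 1.
    """
    if dose_rate_target <= 0:
        raise ValueError("dose_rate_target must be > 0")
    fractions = np.array([m[2] for m in species_mix], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("species_mix dose fractions must sum to 1")
    energy = _ENERGY_GRID if energy_grid is None else np.asarray(energy_grid, float)
    shape = _spectrum_shape(energy)
    target_gy = dose_rate_target * 1e-3
    components = []
    for _, z, fraction in species_mix:
        if fraction == 0.0:
            continue
        unit = FluxComponent(z=z, energy=energy, phi=shape)
        unit_dose = ParticleFlux((unit,)).absorbed_dose()
        components.append(
            FluxComponent(z=z, energy=energy, phi=shape * (fraction * target_gy / unit_dose))
        )
    return ParticleFlux(tuple(components))


@dataclass(frozen=True)
class MissionSegment:
    label: str
    duration_days: float
    flux: ParticleFlux            # daily flux (fluence per day)
    attenuation: float = 1.0      # multiplicative flux attenuation

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValueError("segment duration must be > 0")
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")


@dataclass(frozen=True)
class MissionProfile:
    """Ordered mission segments behind a nominal shielding configuration."""

    name: str
    segments: tuple
    shield_label: str = "20 g/cm^2 aluminum"
    solar_condition: str = "average solar minimum"

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("profile needs at least one segment")

    @property
    def total_duration_days(self) -> float:
        return sum(s.duration_days for s in self.segments)


def gcr_one_year(dose_rate: float = SOLAR_MIN_DOSE_RATE) -> MissionProfile:
    """1-year GCR exposure near average solar minimum."""
    return MissionProfile(
        name="gcr-1yr-solarmin",
        segments=(MissionSegment("free space", 365.0, make_gcr_flux(dose_rate)),),
    )


def mars_mission(
    dose_rate: float = SOLAR_MIN_DOSE_RATE,
    transit_days: float = 400.0,
    surface_days: float = 540.0,
    surface_attenuation: float = MARS_SURFACE_ATTENUATION,
) -> MissionProfile:
    """940-day Mars design reference: 400 days transit + 540 days on surface."""
    flux = make_gcr_flux(dose_rate)
    return MissionProfile(
        name="mars-940d",
        segments=(
            MissionSegment("transit", transit_days, flux),
            MissionSegment("surface", surface_days, flux, attenuation=surface_attenuation),
        ),
    )


PROFILES = {"gcr-1yr-solarmin": gcr_one_year, "mars-940d": mars_mission}


def profile_from_yaml(source) -> MissionProfile:
    """Build a :class:`MissionProfile` from a scenario YAML file or mapping.

    Expected layout: a ``mission:`` block with ``name``,
    ``dose_rate_mgy_per_day`` and a list of ``segments`` each holding
    ``label``, ``duration_days`` and optional ``attenuation``.  The two
    shipped presets live in the package config directory.
    """
    import yaml

    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    mission = raw["mission"]
    flux = make_gcr_flux(float(mission.get("dose_rate_mgy_per_day", SOLAR_MIN_DOSE_RATE)))
    segments = tuple(
        MissionSegment(
            label=str(seg["label"]),
            duration_days=float(seg["duration_days"]),
            flux=flux,
            attenuation=float(seg.get("attenuation", 1.0)),
        )
        for seg in mission["segments"]
    )
    return MissionProfile(
        name=str(mission.get("name", "custom")),
        segments=segments,
        shield_label=str(mission.get("shield_label", "20 g/cm^2 aluminum")),
        solar_condition=str(mission.get("solar_condition", "average solar minimum")),
    )


def preset_profile_yaml(name: str) -> MissionProfile:
    """Load one of the shipped scenario YAML presets by name."""
    from importlib import resources

    text = resources.files("spacerisk.config").joinpath(f"{name}.yaml").read_text()
    import yaml

    return profile_from_yaml(yaml.safe_load(text))


def mission_exposure(
    profile: MissionProfile,
    crew_age_at_start: float,
    mode: str = "TE",
    qf_solid: quality.QFParams | None = None,
    qf_leukemia: quality.QFParams | None = None,
    nte: quality.NTEParams | None = None,
) -> ExposureSchedule:
    """Turn a mission profile into an exposure schedule for the risk engine.

    Each segment becomes one acute event at its midpoint age carrying the
    gamma-equivalent hazard scalars of its cumulative fluence (duration x
    daily flux x attenuation), evaluated separately with the solid-cancer
    and leukemia quality-factor parameter sets.
    """
    qf_solid = qf_solid or quality.default_qf_params("solid")
    qf_leukemia = qf_leukemia or quality.default_qf_params("leukemia")
    if mode == "NTE" and nte is None:
        nte = quality.default_nte_params()
    end_age = crew_age_at_start + profile.total_duration_days / 365.0
    if end_age > AGE_MAX:
        raise ValueError(f"mission extends beyond age {AGE_MAX} (ends at {end_age:.1f})")
    events = []
    elapsed = 0.0
    for seg in profile.segments:
        midpoint_age = crew_age_at_start + (elapsed + seg.duration_days / 2.0) / 365.0
        cumulative = seg.flux.scaled(seg.duration_days * seg.attenuation)
        events.append(
            ExposureEvent(
                exposure_age=midpoint_age,
                h_solid=quality.gamma_equivalent_dose(cumulative, qf_solid, mode, nte),
                h_leukemia=quality.gamma_equivalent_dose(cumulative, qf_leukemia, mode, nte),
                absorbed_dose=cumulative.absorbed_dose(),
            )
        )
        elapsed += seg.duration_days
    return ExposureSchedule(tuple(events), mode=mode)
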