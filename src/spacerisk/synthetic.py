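"""Synthetic populations: calibrated life tables and cancer-rate tables.

Real surveillance data (CDC life tables, SEER delay-adjusted rates) are not
bundled; this module generates stand-ins with the statistical structure the
risk analysis assumes, calibrated to published summary targets:

* all-cause mortality follows a Gompertz-Makeham hazard
  mu(a) = c + b * exp(theta * a), with the senescent scale ``b`` solved by
  one-dimensional root finding so that life expectancy at birth hits the
  population's target;
* tissue-specific incidence follows power-law onset curves (bimodal
  childhood/old-age curve for leukemia), jointly scaled so the age-adjusted
  total matches the population's target exactly; mortality is incidence
  times a per-tissue ratio in (0, 1/1.1].

Everything is deterministic — calibration, not simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .population import (
    AGES,
    CancerRateTable,
    LifeTable,
    age_adjusted_rate,
    apply_mortality_correction,
    life_expectancy,
    tissues_for_sex,
)

#: Gompertz-Makeham defaults: age-independent (accident) hazard and
#: senescent doubling slope.  Only ``b`` is calibrated.
MAKEHAM_C = 5e-4
GOMPERTZ_THETA = 0.095


def _tissue_config() -> dict:
    text = resources.files("spacerisk.config").joinpath("tissue_defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class PopulationSpec:
    """Calibration targets and composition for one synthetic population."""

    population_label: str
    sex: str
    target_life_expectancy: float
    target_age_adjusted_total: float
    tissue_mix: dict = field(default_factory=dict)
    mortality_to_incidence: dict = field(default_factory=dict)

    def __post_init__(self):
        cfg = _tissue_config()
        if not self.tissue_mix:
            object.__setattr__(self, "tissue_mix", dict(cfg["tissue_mix"][self.sex]))
        if not self.mortality_to_incidence:
            object.__setattr__(
                self, "mortality_to_incidence", dict(cfg["mortality_to_incidence"])
            )
        if self.target_life_expectancy <= 0 or self.target_age_adjusted_total <= 0:
            raise ValueError("calibration targets must be positive")
        mix = np.array(list(self.tissue_mix.values()), dtype=float)
        if np.any(mix < 0):
            raise ValueError("tissue_mix fractions must be >= 0")
        # normalise so callers can pass unnormalised weights
        total = mix.sum()
        if total <= 0:
            raise ValueError("tissue_mix must have positive total")
        object.__setattr__(
            self,
            "tissue_mix",
            {t: f / total for t, f in self.tissue_mix.items()},
        )
        allowed = set(tissues_for_sex(self.sex))
        bad = set(self.tissue_mix) - allowed
        if bad:
            raise ValueError(f"tissue_mix has sites not applicable to {self.sex}: {sorted(bad)}")


def load_preset_specs() -> dict[str, PopulationSpec]:
    """The eight shipped population presets (4 groups x 2 sexes)."""
    text = resources.files("spacerisk.config").joinpath("populations.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        key: PopulationSpec(
            population_label=row["population"],
            sex=row["sex"],
            target_life_expectancy=row["life_expectancy"],
            target_age_adjusted_total=row["age_adjusted_total"],
        )
        for key, row in raw.items()
    }


def preset_spec(name: str) -> PopulationSpec:
    specs = load_preset_specs()
    try:
        return specs[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(specs)}") from None


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------


def _gm_life_table(spec: PopulationSpec, b: float) -> LifeTable:
    hazard = MAKEHAM_C + b * np.exp(GOMPERTZ_THETA * AGES)
    return LifeTable.from_hazard(spec.population_label, spec.sex, hazard)


def make_life_table(spec: PopulationSpec, tolerance: float = 0.1) -> LifeTable:
    """Gompertz-Makeham life table calibrated to the target life expectancy.

    Solves for the senescent scale ``b`` by bracketing root finding;
    deterministic given the spec.  Raises if the target is infeasible for
    the fixed Makeham constant and slope (e.g. above the near-zero-mortality
    bound set by the age-100 cutoff).
    """
    target = spec.target_life_expectancy
    lo, hi = 1e-12, 1.0

    def gap(log_b):
        return life_expectancy(_gm_life_table(spec, np.exp(log_b)), 0) - target

    g_lo, g_hi = gap(np.log(lo)), gap(np.log(hi))
    if not (g_lo > 0 > g_hi):
        raise ValueError(
            f"life-expectancy target {target} y infeasible for "
            f"Gompertz-Makeham(c={MAKEHAM_C}, theta={GOMPERTZ_THETA})"
        )
    log_b = brentq(gap, np.log(lo), np.log(hi), xtol=1e-12)
    table = _gm_life_table(spec, float(np.exp(log_b)))
    achieved = life_expectancy(table, 0)
    if abs(achieved - target) > tolerance:
        raise ValueError(
            f"calibration missed target {target} y (achieved {achieved:.3f})"
        )
    return table


# ---------------------------------------------------------------------------
# Cancer rates
# ---------------------------------------------------------------------------


def _unit_shape(tissue: str, cfg: dict) -> np.ndarray:
    """Unnormalised age-specific incidence shape on ages 0..100.

    Power-law onset curves multiplied by a logistic old-age roll-off
    (delay-adjusted surveillance incidence flattens and declines above ~85,
    and without the taper lifetime cumulative incidence is implausibly
    large).  Leukemia gets a bimodal childhood/old-age curve instead.
    """
    a = AGES.astype(float)
    taper = 1.0 / (1.0 + np.exp((a - 80.0) / 6.0))
    if tissue == "leukemia":
        # childhood peak near age 4 plus an old-age rise
        return (2.0 * np.exp(-(((a - 4.0) / 4.0) ** 2)) + (a / 60.0) ** 3) * taper
    shape = cfg["incidence_shape"][tissue]
    return np.maximum(a - shape["onset"], 0.0) ** shape["power"] * taper


def make_cancer_rates(spec: PopulationSpec, life_table: LifeTable) -> CancerRateTable:
    """Rate table whose age-adjusted total matches the spec target.

    Each tissue's incidence curve is its unit shape scaled so that (a) the
    tissue contributes its ``tissue_mix`` fraction of the age-adjusted total
    and (b) the total equals the target (the scaling is exact because rates
    are linear in the per-tissue amplitudes).  Mortality is incidence times
    the per-tissue mortality-to-incidence ratio, then passed through the
    consistency correction (a no-op when every ratio is <= 1/1.1).
    """
    if life_table.population_label != spec.population_label or life_table.sex != spec.sex:
        raise ValueError("spec and life table refer to different populations")
    cfg = _tissue_config()
    incidence, mortality = {}, {}
    for tissue, fraction in spec.tissue_mix.items():
        shape = _unit_shape(tissue, cfg)
        adj = age_adjusted_rate(shape)
        if adj <= 0:
            raise ValueError(f"degenerate incidence shape for {tissue}")
        lam = shape * (fraction * spec.target_age_adjusted_total / adj)
        ratio = spec.mortality_to_incidence.get(tissue)
        if ratio is None:
            raise KeyError(f"no mortality_to_incidence ratio for {tissue}")
        if not (0 < ratio <= 1 / 1.1 + 1e-12):
            raise ValueError(f"mortality_to_incidence for {tissue} must be in (0, 1/1.1]")
        incidence[tissue] = lam
        mortality[tissue] = lam * ratio
    table = CancerRateTable(spec.population_label, spec.sex, incidence, mortality)
    return apply_mortality_correction(table)


def make_population(name_or_spec) -> tuple[LifeTable, CancerRateTable]:
    """Convenience: build both calibrated tables for a preset name or spec."""
    spec = preset_spec(name_or_spec) if isinstance(name_or_spec, str) else name_or_spec
    table = make_life_table(spec)
    return table, make_cancer_rates(spec, table)
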