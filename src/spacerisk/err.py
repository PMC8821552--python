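"""Excess-relative-risk (ERR) models for radiogenic cancer.

Solid cancers follow the Life Span Study parametric form

    ERR(D, a, aE) = rho * D * (a/70)^eta * exp[gamma * (aE - 30)],

linear in dose D (Gy), with attained-age power ``eta`` and an exponential
age-at-exposure modifier ``gamma`` (per year).  Both modifiers equal 1 at the
reference point a = 70, aE = 30, so ``rho`` is the ERR per Gy there.

Leukemia (excluding CLL) replaces the age-at-exposure modifier with a
time-since-exposure factor.  Two readings of the published model are
supported: a power law ((a-aE)/40)^upsilon (default, matching the tabulated
"power -0.81") and an exponential exp[upsilon*(a-aE)/40].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .population import FEMALE_ONLY, MALE_ONLY, TISSUES

#: Tissues explicitly excluded from risk totals.
EXCLUDED_TISSUES = frozenset({"uterus"})

#: Minimum latency in years between exposure and any radiogenic contribution.
MIN_LATENCY = {"solid": 5.0, "leukemia": 2.0}


@dataclass(frozen=True)
class ERRParams:
    """ERR model parameters for one tissue and sex."""

    tissue: str
    sex: str
    rho: float                      # ERR per Gy at the reference point
    eta: float = 0.0                # attained-age power
    gamma: float = 0.0              # age-at-exposure coefficient, per year
    upsilon: float = 0.0            # time-since-exposure exponent (leukemia)
    ci_rho: tuple | None = None     # reported 95% interval for rho
    form: str = "solid"             # {"solid", "leukemia"}
    leukemia_time_form: str = "power"   # {"power", "exponential"}

    def __post_init__(self):
        if not np.isfinite(self.rho):
            raise ValueError("rho must be finite")
        if self.form not in ("solid", "leukemia"):
            raise ValueError(f"unknown ERR form {self.form!r}")


def err_solid(params: ERRParams, dose, attained_age, exposure_age):
    """Evaluate the solid-cancer ERR model; vectorised over any argument."""
    if params.form != "solid":
        raise ValueError(f"{params.tissue}: err_solid requires a solid-form entry")
    dose = np.asarray(dose, dtype=float)
    a = np.asarray(attained_age, dtype=float)
    a_e = np.asarray(exposure_age, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if np.any(a < a_e):
        raise ValueError("attained age must be >= exposure age")
    out = params.rho * dose * (a / 70.0) ** params.eta * np.exp(params.gamma * (a_e - 30.0))
    return out if out.ndim else float(out)


def err_leukemia(params: ERRParams, dose, attained_age, exposure_age):
    """Evaluate the leukemia ERR model (time-since-exposure dependence).

    Callers must gate on the minimum latency; evaluating below it raises.
    """
    if params.form != "leukemia":
        raise ValueError(f"{params.tissue}: err_leukemia requires a leukemia-form entry")
    dose = np.asarray(dose, dtype=float)
    a = np.asarray(attained_age, dtype=float)
    a_e = np.asarray(exposure_age, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    lat = a - a_e
    if np.any(lat < MIN_LATENCY["leukemia"]):
        raise ValueError(
            f"latency below the {MIN_LATENCY['leukemia']}-year leukemia minimum"
        )
    if params.leukemia_time_form == "power":
        time_factor = (lat / 40.0) ** params.upsilon
    elif params.leukemia_time_form == "exponential":
        time_factor = np.exp(params.upsilon * lat / 40.0)
    else:
        raise ValueError(f"unknown leukemia time form {params.leukemia_time_form!r}")
    out = params.rho * dose * (a / 70.0) ** params.eta * time_factor
    return out if out.ndim else float(out)


def err_value(params: ERRParams, dose, attained_age, exposure_age):
    """Dispatch to the solid or leukemia form."""
    if params.form == "leukemia":
        return err_leukemia(params, dose, attained_age, exposure_age)
    return err_solid(params, dose, attained_age, exposure_age)


def percent_decline_per_decade(gamma: float) -> float:
    """Percent decline of ERR per decade of age at exposure: 100*(1 - e^{10*gamma}).

    Negative values mean the ERR *increases* with age at exposure.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    return 100.0 * (1.0 - np.exp(10.0 * gamma))


class ERRRegistry:
    """Tissue x sex registry of :class:`ERRParams` loaded from config."""

    def __init__(self, entries: dict[tuple[str, str], ERRParams]):
        self._entries = entries

    @classmethod
    def from_config(cls, raw: dict, leukemia_time_form: str = "power") -> "ERRRegistry":
        entries = {}
        for tissue, row in raw.items():
            for sex, rho in row["rho"].items():
                ci = row.get("ci_rho", {}).get(sex)
                entries[(tissue, sex)] = ERRParams(
                    tissue=tissue,
                    sex=sex,
                    rho=float(rho),
                    eta=float(row.get("eta", 0.0)),
                    gamma=float(row.get("gamma", 0.0)),
                    upsilon=float(row.get("upsilon", 0.0)),
                    ci_rho=tuple(ci) if ci else None,
                    form=row.get("form", "solid"),
                    leukemia_time_form=leukemia_time_form,
                )
        return cls(entries)

    @classmethod
    def default(cls, leukemia_time_form: str = "power") -> "ERRRegistry":
        """Registry shipped with the package (config/err_params.yaml)."""
        text = resources.files("spacerisk.config").joinpath("err_params.yaml").read_text()
        return cls.from_config(yaml.safe_load(text), leukemia_time_form)

    def get(self, tissue: str, sex: str) -> ERRParams:
        try:
            return self._entries[(tissue, sex)]
        except KeyError:
            raise KeyError(f"no ERR parameters for tissue {tissue!r}, sex {sex!r}") from None

    def has(self, tissue: str, sex: str) -> bool:
        return (tissue, sex) in self._entries

    def tissues(self, sex: str) -> tuple[str, ...]:
        """Risk-contributing tissues for one sex, in canonical order."""
        return tuple(t for t in TISSUES if (t, sex) in self._entries and t != "all_solid")

    def with_rho(self, overrides: dict[tuple[str, str], float]) -> "ERRRegistry":
        """Copy of the registry with some rho values replaced (for sampling)."""
        from dataclasses import replace

        entries = dict(self._entries)
        for key, rho in overrides.items():
            entries[key] = replace(entries[key], rho=float(rho))
        return ERRRegistry(entries)

    def validate_against(self, tissue_list) -> None:
        """Check every rate-table tissue maps to exactly one entry per sex."""
        for t in tissue_list:
            if t in EXCLUDED_TISSUES:
                continue
            sexes = ("female",) if t in FEMALE_ONLY else ("male",) if t in MALE_ONLY else ("female", "male")
            for s in sexes:
                if not self.has(t, s):
                    raise KeyError(f"ERR registry missing tissue {t!r} for sex {s!r}")


def fm_ratio(tissue: str, registry: ERRRegistry | None = None) -> float:
    """Female-to-male ERR ratio at the reference point (D=1 Gy, a=70, aE=30).

    With attained-age and exposure-age modifiers shared between sexes this
    reduces to rho_F / rho_M.
    """
    registry = registry or ERRRegistry.default()
    if tissue in FEMALE_ONLY or tissue in MALE_ONLY:
        raise ValueError(f"{tissue} is sex-specific; no F/M ratio")
    f = registry.get(tissue, "female")
    m = registry.get(tissue, "male")
    if f.form == "leukemia":
        num = err_leukemia(f, 1.0, 70.0, 30.0)
        den = err_leukemia(m, 1.0, 70.0, 30.0)
    else:
        num = err_solid(f, 1.0, 70.0, 30.0)
        den = err_solid(m, 1.0, 70.0, 30.0)
    return num / den
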