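"""Life tables and background cancer-rate tables.

The whole package works on an integer age grid 0..100 with rates treated as
piecewise-constant over each one-year interval [a, a+1).  Survival follows the
exponential-within-year convention

    S0(a) = exp(-sum_{k<a} h(k)),

so the hazard ``h`` and survival ``S0`` are mutually recoverable in closed
form.  Cancer rates are stored per 100,000 person-years (the scale on which
surveillance programmes publish them) and converted to per person-year in
exactly one place (:func:`per_person_year`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer age grid; all integrals and expectations truncate at age 100.
AGE_MAX = 100
AGES = np.arange(AGE_MAX + 1)

RATE_DENOMINATOR = 100_000.0

#: Solid-cancer sites plus leukemia (excluding CLL).  "other" is the
#: remainder group.  Uterine cancer is excluded (risk contribution small).
SOLID_TISSUES = (
    "lung",
    "stomach",
    "colon",
    "liver",
    "urinary_bladder",
    "esophagus",
    "brain",
    "pancreas",
    "breast",
    "ovary",
    "prostate",
    "thyroid",
    "other",
)
TISSUES = SOLID_TISSUES + ("leukemia",)

FEMALE_ONLY = frozenset({"breast", "ovary"})
MALE_ONLY = frozenset({"prostate"})


def tissues_for_sex(sex: str) -> tuple[str, ...]:
    """Tissue sites applicable to one sex."""
    if sex == "female":
        return tuple(t for t in TISSUES if t not in MALE_ONLY)
    if sex == "male":
        return tuple(t for t in TISSUES if t not in FEMALE_ONLY)
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


def per_person_year(rate_per_100k: np.ndarray | float) -> np.ndarray | float:
    """Convert a rate per 100,000 person-years to per person-year."""
    return np.asarray(rate_per_100k, dtype=float) / RATE_DENOMINATOR


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """All-cause mortality for one population and sex on ages 0..100.

    Parameters
    ----------
    population_label : str
        Free-text population identifier (e.g. ``"white"``).
    sex : str
        ``"female"`` or ``"male"``.
    hazard : ndarray
        All-cause mortality rate per person-year at each integer age.
    survival : ndarray
        S0(a), probability of being alive at age a; ``survival[0] == 1``.
    """

    population_label: str
    sex: str
    hazard: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        hazard = np.asarray(self.hazard, dtype=float)
        survival = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "hazard", hazard)
        object.__setattr__(self, "survival", survival)
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if hazard.shape != AGES.shape or survival.shape != AGES.shape:
            raise ValueError("hazard and survival must cover ages 0..100")
        if np.any(hazard < 0):
            raise ValueError("negative hazard")
        if abs(survival[0] - 1.0) > 1e-12:
            raise ValueError("S0(0) must equal 1")
        if np.any(np.diff(survival) > 1e-15):
            raise ValueError("survival must be non-increasing")

    @classmethod
    def from_hazard(cls, population_label: str, sex: str, hazard: np.ndarray) -> "LifeTable":
        """Build a table from a hazard curve; survival follows the
        exponential-within-year convention."""
        hazard = np.asarray(hazard, dtype=float)
        if hazard.shape != AGES.shape:
            raise ValueError("hazard must cover ages 0..100")
        survival = np.empty_like(hazard)
        survival[0] = 1.0
        survival[1:] = np.exp(-np.cumsum(hazard[:-1]))
        return cls(population_label, sex, hazard, survival)

    @classmethod
    def from_survival(cls, population_label: str, sex: str, survival: np.ndarray) -> "LifeTable":
        """Build a table from a survival curve by inverting the
        exponential-within-year convention.

        The hazard at the final age (100) is unconstrained by S0 on the grid
        and is carried forward from age 99 (closure rule).
        """
        survival = np.asarray(survival, dtype=float)
        if survival.shape != AGES.shape:
            raise ValueError("survival must cover ages 0..100")
        if np.any(survival <= 0):
            raise ValueError("survival must be positive to recover a finite hazard")
        hazard = np.empty_like(survival)
        hazard[:-1] = -np.diff(np.log(survival))
        hazard[-1] = hazard[-2]
        return cls(population_label, sex, hazard, survival)


def read_life_table(path) -> LifeTable:
    """Read a life table from CSV.

    Expected columns: ``age`` plus ``hazard`` and/or ``survival``.  Metadata
    (population, sex) comes from ``#``-prefixed header comment lines of the
    form ``# key: value`` or from a ``<path>.json`` sidecar.
    """
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "age" not in df.columns:
        raise ValueError("life table CSV needs an 'age' column")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    missing = sorted(set(AGES.tolist()) - set(ages.tolist()))
    if missing:
        raise ValueError(f"life table missing ages: {_summarize_gaps(missing)}")
    label = meta.get("population", "unknown")
    sex = meta.get("sex", "female")
    if "hazard" in df.columns:
        table = LifeTable.from_hazard(label, sex, df["hazard"].to_numpy(dtype=float))
        if "survival" in df.columns:
            declared = df["survival"].to_numpy(dtype=float)
            if not np.allclose(declared, table.survival, rtol=1e-6, atol=1e-9):
                raise ValueError("declared survival inconsistent with hazard")
        return table
    if "survival" in df.columns:
        return LifeTable.from_survival(label, sex, df["survival"].to_numpy(dtype=float))
    raise ValueError("life table CSV needs a 'hazard' or 'survival' column")


def write_life_table(table: LifeTable, path) -> None:
    """Write a life table as CSV with metadata comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# population: {table.population_label}\n")
        fh.write(f"# sex: {table.sex}\n")
        fh.write("age,hazard,survival\n")
        for a in AGES:
            fh.write(f"{a},{float(table.hazard[a])!r},{float(table.survival[a])!r}\n")


def life_expectancy(table: LifeTable, from_age: int = 0) -> float:
    """Expected age at death, conditional on being alive at ``from_age``.

    Under the piecewise-constant hazard convention, the expected fraction of
    year [a, a+1) lived by someone alive at a is (1 - e^{-h}) / h, so the
    conditional remaining lifetime (truncated at 100) is

        sum_{a=from}^{99} S0(a)/S0(from) * (1 - e^{-h(a)}) / h(a).

    For a constant hazard this reproduces the continuous closed form
    (1 - e^{-100 mu}) / mu exactly.
    """
    if not (0 <= from_age <= AGE_MAX):
        raise ValueError(f"from_age {from_age} outside age grid 0..{AGE_MAX}")
    from_age = int(from_age)
    h = table.hazard[from_age:AGE_MAX]
    s = table.survival[from_age:AGE_MAX]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(h > 0, -np.expm1(-h) / np.where(h > 0, h, 1.0), 1.0)
    remaining = float(np.sum(s * frac) / table.survival[from_age])
    return from_age + remaining


# ---------------------------------------------------------------------------
# Cancer-rate tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CancerRateTable:
    """Tissue-specific background incidence and mortality rates.

    ``incidence`` and ``mortality`` map tissue -> ndarray of rates per
    100,000 person-years on ages 0..100.
    """

    population_label: str
    sex: str
    incidence: dict = field(default_factory=dict)
    mortality: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        # "all_solid" is allowed as an aggregate row for toy/diagnostic tables
        allowed = set(tissues_for_sex(self.sex)) | {"all_solid"}
        for name, store in (("incidence", self.incidence), ("mortality", self.mortality)):
            for tissue, arr in store.items():
                if tissue not in allowed:
                    raise ValueError(
                        f"tissue {tissue!r} not applicable to sex {self.sex!r}"
                    )
                arr = np.asarray(arr, dtype=float)
                store[tissue] = arr
                if arr.shape != AGES.shape:
                    raise ValueError(f"{name}[{tissue}] must cover ages 0..100")
                if np.any(arr < 0):
                    raise ValueError(f"negative {name} rate for {tissue}")
        if set(self.incidence) != set(self.mortality):
            raise ValueError("incidence and mortality must list the same tissues")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted(self.incidence))

    def total_incidence(self) -> np.ndarray:
        """Sum of incidence over tissues (per 100,000)."""
        return np.sum([self.incidence[t] for t in self.tissues], axis=0)


def read_cancer_rates(path) -> CancerRateTable:
    """Read a rate table from CSV with columns ``age,tissue,incidence,mortality``."""
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    needed = {"age", "tissue", "incidence", "mortality"}
    if not needed <= set(df.columns):
        raise ValueError(f"rate CSV needs columns {sorted(needed)}")
    incidence, mortality = {}, {}
    for tissue, grp in df.groupby("tissue"):
        grp = grp.sort_values("age")
        missing = sorted(set(AGES.tolist()) - set(grp["age"].tolist()))
        if missing:
            raise ValueError(f"{tissue}: missing ages {_summarize_gaps(missing)}")
        incidence[tissue] = grp["incidence"].to_numpy(dtype=float)
        mortality[tissue] = grp["mortality"].to_numpy(dtype=float)
    return CancerRateTable(
        meta.get("population", "unknown"), meta.get("sex", "female"), incidence, mortality
    )


def write_cancer_rates(rates: CancerRateTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# population: {rates.population_label}\n")
        fh.write(f"# sex: {rates.sex}\n")
        fh.write("age,tissue,incidence,mortality\n")
        for tissue in rates.tissues:
            inc, mor = rates.incidence[tissue], rates.mortality[tissue]
            for a in AGES:
                fh.write(f"{a},{tissue},{float(inc[a])!r},{float(mor[a])!r}\n")


def apply_mortality_correction(
    rates: CancerRateTable, incidence_excess: float = 1.1
) -> CancerRateTable:
    """Cap mortality so incidence exceeds it by ``incidence_excess`` (default 10%).

    Delay-adjusted incidence rates can fall below registered mortality at old
    ages; wherever mortality > incidence / incidence_excess the mortality is
    replaced by incidence / incidence_excess.  Idempotent; the number of
    corrected cells is logged.
    """
    new_mortality = {}
    corrected = 0
    for tissue in rates.tissues:
        cap = rates.incidence[tissue] / incidence_excess
        m = rates.mortality[tissue]
        over = m > cap
        corrected += int(np.count_nonzero(over))
        new_mortality[tissue] = np.where(over, cap, m)
    logger.info("mortality correction adjusted %d cells", corrected)
    return replace(rates, mortality=new_mortality)


# Approximate year-2000 U.S. standard population by 5-year age group (per
# million, 85+ pooled), used to weight age-specific rates into a single
# age-adjusted number.  The standard's published group totals are mapped onto
# single years of age uniformly within each group.
_STANDARD_GROUPS = [
    ((0, 0), 13818),
    ((1, 4), 55317),
    ((5, 9), 72533),
    ((10, 14), 73032),
    ((15, 19), 72169),
    ((20, 24), 66478),
    ((25, 29), 64529),
    ((30, 34), 71044),
    ((35, 39), 80762),
    ((40, 44), 81851),
    ((45, 49), 72118),
    ((50, 54), 62716),
    ((55, 59), 48454),
    ((60, 64), 38793),
    ((65, 69), 34264),
    ((70, 74), 31773),
    ((75, 79), 26999),
    ((80, 84), 17842),
    ((85, 100), 15508),
]


def standard_age_weights() -> np.ndarray:
    """Default age-standardisation weights on ages 0..100 (sum to 1)."""
    w = np.zeros_like(AGES, dtype=float)
    for (lo, hi), count in _STANDARD_GROUPS:
        w[lo : hi + 1] = count / (hi - lo + 1)
    return w / w.sum()


def age_adjusted_rate(
    age_specific: np.ndarray, standard_weights: np.ndarray | None = None
) -> float:
    """Weighted sum of age-specific rates over a standard age distribution.

    ``age_specific`` is any rate curve on ages 0..100 (per 100,000); weights
    default to :func:`standard_age_weights` and must sum to 1.
    """
    age_specific = np.asarray(age_specific, dtype=float)
    w = standard_age_weights() if standard_weights is None else np.asarray(standard_weights, float)
    if w.shape != age_specific.shape:
        raise ValueError("weights and rate grid have mismatched shapes")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("standard weights must sum to 1")
    return float(np.dot(w, age_specific))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_metadata(path) -> dict:
    meta = {}
    sidecar = f"{path}.json"
    try:
        with open(sidecar) as fh:
            meta.update(json.load(fh))
    except FileNotFoundError:
        pass
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def _summarize_gaps(missing: list) -> str:
    if len(missing) <= 8:
        return str(missing)
    return f"{missing[:8]}... ({len(missing)} ages)"
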