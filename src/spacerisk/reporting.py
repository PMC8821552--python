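"""Run orchestration: scenario execution, age scans, population comparisons.

These functions are the library face of the command-line interface: each
takes a :class:`RunConfig`, builds the synthetic population, assembles the
mission exposure schedule and runs the risk engine, optionally with
Monte-Carlo intervals.  Results are plain :class:`~spacerisk.engine.RiskResult`
objects; writers serialise them to JSON/CSV with enough provenance to
re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from . import scenarios, uncertainty
from .engine import RiskResult, compute_risk
from .err import ERRRegistry
from .quality import NTEParams, QFParams, default_nte_params, default_qf_params
from .synthetic import make_population, preset_spec


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end run: population preset, scenario, mode, MC settings."""

    population: str                   # preset key, e.g. "white_female"
    scenario: str = "gcr-1yr-solarmin"
    mode: str = "TE"                  # {"TE", "NTE"}
    exposure_age: float = 35.0
    mc_trials: int = 0                # 0 = point estimate only
    seed: int = 0
    percentiles: tuple = (2.5, 97.5)
    inner_bound: str = "event"

    def __post_init__(self):
        if self.mode not in ("TE", "NTE"):
            raise ValueError("mode must be 'TE' or 'NTE'")
        if self.scenario not in scenarios.PROFILES:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(scenarios.PROFILES)}"
            )
        preset_spec(self.population)  # raises on unknown preset

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentiles"] = list(self.percentiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _engine_call_factory(config: RunConfig, registry: ERRRegistry):
    """Build the closure mc_interval re-runs per parameter bundle."""
    life_table, rates = make_population(config.population)
    profile = scenarios.PROFILES[config.scenario]()

    def call(bundle) -> RiskResult:
        if bundle is None:
            qf_s = default_qf_params("solid")
            qf_l = default_qf_params("leukemia")
            nte = default_nte_params() if config.mode == "NTE" else None
            reg = registry
            flux_scale = 1.0
        else:
            base_s = default_qf_params("solid")
            base_l = default_qf_params("leukemia")
            qf_s = QFParams(base_s.sigma0_over_alpha * bundle["qf_scale"], base_s.kappa,
                            base_s.m, bundle["ddref"], "solid")
            qf_l = QFParams(base_l.sigma0_over_alpha * bundle["qf_scale"], base_l.kappa,
                            base_l.m, bundle["ddref"], "leukemia")
            nte = None
            if config.mode == "NTE":
                base_n = default_nte_params()
                nte = NTEParams(base_n.eta0_over_alpha * bundle["nte_scale"],
                                base_n.eta1, base_n.a_bys)
            reg = registry.with_rho(
                {k: v for k, v in bundle["rho"].items() if registry.has(*k)}
            )
            flux_scale = bundle["flux_scale"]
        schedule = scenarios.mission_exposure(
            profile, config.exposure_age, config.mode, qf_s, qf_l, nte
        )
        if flux_scale != 1.0:
            schedule = replace(
                schedule,
                events=tuple(
                    replace(e, h_solid=e.h_solid * flux_scale,
                            h_leukemia=e.h_leukemia * flux_scale,
                            absorbed_dose=e.absorbed_dose * flux_scale)
                    for e in schedule.events
                ),
            )
        return compute_risk(schedule, life_table, rates, reg, inner_bound=config.inner_bound)

    return call


def run_scenario(config: RunConfig, registry: ERRRegistry | None = None) -> RiskResult:
    """Execute one configured run; MC intervals when ``mc_trials`` > 0."""
    registry = registry or ERRRegistry.default()
    call = _engine_call_factory(config, registry)
    if config.mc_trials > 0:
        sex = preset_spec(config.population).sex
        pdfs = uncertainty.default_pdf_set(registry, sex=sex, master_seed=config.seed)
        result = uncertainty.mc_interval(call, pdfs, config.mc_trials, config.percentiles)
    else:
        result = call(None)
    prov = dict(result.provenance)
    prov.update({"scenario": config.scenario, "config": config.to_dict(),
                 "config_hash": _config_hash(config)})
    return replace(result, provenance=prov)


def age_scan(config: RunConfig, ages, registry: ERRRegistry | None = None) -> pd.DataFrame:
    """REIC/REID totals versus exposure age; one row per age."""
    ages = list(ages)
    if not ages:
        raise ValueError("age list must not be empty")
    rows = []
    for age in ages:
        res = run_scenario(replace(config, exposure_age=float(age)), registry)
        rows.append({"exposure_age": float(age),
                     "total_reic_pct": res.total_reic,
                     "total_reid_pct": res.total_reid})
    return pd.DataFrame(rows)


def compare_populations(configs, registry: ERRRegistry | None = None) -> pd.DataFrame:
    """Rank >= 2 runs of the same scenario by total REIC.

    Returns one row per population with totals, rank (1 = highest risk,
    average rank on ties) and per-tissue risks.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    if len({(c.scenario, c.mode, c.exposure_age) for c in configs}) != 1:
        raise ValueError("compared runs must share scenario, mode and exposure age")
    rows = []
    for config in configs:
        res = run_scenario(config, registry)
        row = {"population": config.population,
               "total_reic_pct": res.total_reic,
               "total_reid_pct": res.total_reid}
        row.update({f"reic_{t}": v for t, v in res.reic.items() if t != "total"})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["rank"] = df["total_reic_pct"].rank(ascending=False)
    return df.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def result_to_dict(result: RiskResult) -> dict:
    return {
        "mode": result.mode,
        "reic_pct": result.reic,
        "reid_pct": result.reid,
        "reic_interval_pct": {k: list(v) for k, v in result.reic_interval.items()},
        "reid_interval_pct": {k: list(v) for k, v in result.reid_interval.items()},
        "provenance": result.provenance,
    }


def write_result_json(result: RiskResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_result_csv(result: RiskResult, path) -> None:
    """Per-tissue table (percent, full precision) with optional intervals."""
    tissues = [t for t in result.reic if t != "total"] + ["total"]
    rows = []
    for t in tissues:
        row = {"tissue": t, "reic_pct": result.reic[t], "reid_pct": result.reid[t]}
        if result.reic_interval:
            row["reic_lo"], row["reic_hi"] = result.reic_interval[t]
            row["reid_lo"], row["reid_hi"] = result.reid_interval[t]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
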