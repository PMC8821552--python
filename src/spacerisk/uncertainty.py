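"""Monte-Carlo propagation of parameter uncertainty to REIC/REID intervals.

Probability distributions are attached to the ERR coefficients (fit to the
reported central values and 95% intervals), the DDREF, the quality-factor
and bystander parameters, and an overall flux-scale factor.  Each trial
draws one parameter bundle, re-runs the risk engine, and the empirical
percentiles across trials form the reported interval; the point estimate
always comes from the central (unsampled) parameters.

Distribution families: normal when the reported interval is symmetric about
the central value (or reaches <= 0), lognormal when it is right-skewed.
Sampling uses counter-based Philox substreams keyed by (master seed, trial
index), so trials are order-independent and reproducible one at a time.

By default the DDREF, quality-factor and NTE draws are shared across tissues
within a trial (they describe common physics), while each tissue's ERR
coefficient is drawn independently (they come from separate epidemiological
fits); both choices are switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import quality
from .err import ERRRegistry

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class ParameterPDF:
    """One scalar parameter's sampling distribution."""

    name: str
    family: str          # {"normal", "lognormal", "point"}
    location: float      # central value (mean / median / the point)
    spread: float        # sd (normal) or sd of log (lognormal)
    lower: float | None = None   # optional domain truncation

    def __post_init__(self):
        if self.family not in ("normal", "lognormal", "point"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "point" or self.spread == 0.0:
            return self.location
        for _ in range(1000):
            if self.family == "normal":
                v = rng.normal(self.location, self.spread)
            else:
                v = self.location * np.exp(rng.normal(0.0, self.spread))
            if self.lower is None or v >= self.lower:
                return float(v)
        raise RuntimeError(f"{self.name}: truncated sampling failed to find a value")

    def analytic_mean(self) -> float:
        """Untruncated mean of the fitted family (for calibration checks)."""
        if self.family == "lognormal":
            return self.location * float(np.exp(self.spread**2 / 2.0))
        return self.location

    @classmethod
    def from_interval(cls, name: str, central: float, ci: tuple, skew_threshold: float = 1.2):
        """Fit a family to a central value and 95% interval.

        Right-skewed intervals ((hi-c)/(c-lo) > threshold, all positive) get
        a lognormal with the central value as median; otherwise a normal
        with sd = width / (2 * 1.96).
        """
        lo, hi = float(ci[0]), float(ci[1])
        if not (lo <= central <= hi):
            raise ValueError(f"{name}: interval [{lo}, {hi}] does not bracket {central}")
        if lo > 0 and central > 0:
            skew = (hi - central) / max(central - lo, 1e-12)
            if skew > skew_threshold:
                spread = (np.log(hi) - np.log(lo)) / (2.0 * _Z975)
                return cls(name, "lognormal", central, float(spread))
        return cls(name, "normal", central, (hi - lo) / (2.0 * _Z975))


@dataclass(frozen=True)
class ParameterPDFSet:
    """All sampling distributions plus the master seed."""

    rho: dict                      # (tissue, sex) -> ParameterPDF
    ddref: ParameterPDF
    qf_scale: ParameterPDF         # multiplies sigma0_over_alpha
    nte_scale: ParameterPDF        # multiplies eta0_over_alpha
    flux_scale: ParameterPDF       # multiplies every hazard scalar
    master_seed: int = 0
    share_physics: bool = True     # one DDREF/QF/NTE draw per trial
    independent_rho: bool = True   # per-tissue independent ERR draws

    def zero_spread(self) -> "ParameterPDFSet":
        """Degenerate copy: every trial returns the point estimates."""
        point = lambda p: replace(p, family="point", spread=0.0)
        return replace(
            self,
            rho={k: point(p) for k, p in self.rho.items()},
            ddref=point(self.ddref),
            qf_scale=point(self.qf_scale),
            nte_scale=point(self.nte_scale),
            flux_scale=point(self.flux_scale),
        )


def default_pdf_set(
    registry: ERRRegistry | None = None,
    sex: str | None = None,
    master_seed: int = 0,
) -> ParameterPDFSet:
    """PDF set derived from the shipped ERR intervals and quality config.

    ERR coefficients without a reported interval get a +/-50% normal spread
    (a conservative stand-in).  The flux-scale and QF/NTE spreads are
    placeholder lognormals (the underlying fits are not restated here); NTE
    spreads are deliberately wide.
    """
    registry = registry or ERRRegistry.default()
    cfg = quality.load_quality_config()
    rho = {}
    sexes = (sex,) if sex else ("female", "male")
    for s in sexes:
        for tissue in registry.tissues(s):
            p = registry.get(tissue, s)
            # Negative ERR draws (intervals spanning 0) are truncated at 0:
            # the point-estimate path keeps registry values untouched, but a
            # negative radiogenic rate would invert the REID <= REIC
            # ordering inside a trial.
            if p.ci_rho is not None:
                pdf = ParameterPDF.from_interval(f"rho[{tissue},{s}]", p.rho, p.ci_rho)
                rho[(tissue, s)] = replace(pdf, lower=0.0)
            else:
                rho[(tissue, s)] = ParameterPDF(
                    f"rho[{tissue},{s}]", "normal", p.rho, 0.25 * abs(p.rho), lower=0.0
                )
    dd = cfg["solid"]["ddref_pdf"]
    return ParameterPDFSet(
        rho=rho,
        ddref=ParameterPDF("ddref", dd["family"], dd["median"], float(np.log(dd["gsd"])),
                           lower=dd.get("lower")),
        qf_scale=ParameterPDF("qf_scale", "lognormal", 1.0, 0.25),
        nte_scale=ParameterPDF("nte_scale", "lognormal", 1.0, 0.7),
        flux_scale=ParameterPDF("flux_scale", "lognormal", 1.0, 0.12),
        master_seed=master_seed,
    )


def _trial_rng(master_seed: int, trial_index: int, lane: int = 0) -> np.random.Generator:
    """Counter-based substream: independent of trial execution order."""
    # Philox keys are two 64-bit words: (seed, trial) with the lane packed
    # into the high bits of the second word.
    return np.random.Generator(
        np.random.Philox(key=[master_seed, (lane << 40) + trial_index])
    )


def sample_parameters(pdfs: ParameterPDFSet, trial_index: int) -> dict:
    """Draw one parameter bundle, a pure function of (master seed, trial)."""
    bundle = {}
    rng_phys = _trial_rng(pdfs.master_seed, trial_index, lane=0)
    bundle["ddref"] = pdfs.ddref.sample(rng_phys)
    bundle["qf_scale"] = pdfs.qf_scale.sample(rng_phys)
    bundle["nte_scale"] = pdfs.nte_scale.sample(rng_phys)
    bundle["flux_scale"] = pdfs.flux_scale.sample(rng_phys)
    rho = {}
    for lane, key in enumerate(sorted(pdfs.rho), start=1):
        rng = _trial_rng(pdfs.master_seed, trial_index, lane) if pdfs.independent_rho else rng_phys
        rho[key] = pdfs.rho[key].sample(rng)
    bundle["rho"] = rho
    return bundle


def mc_interval(
    engine_call,
    pdfs: ParameterPDFSet,
    n_trials: int = 1000,
    percentiles=(2.5, 97.5),
) -> "RiskResult":
    """Wrap a risk computation with Monte-Carlo percentile intervals.

    ``engine_call(bundle_or_None)`` must run the full pipeline with the given
    parameter bundle (None means central parameters) and return a
    ``RiskResult``.  Intervals are empirical percentiles across trials; the
    point estimate is the central run.  Non-finite trials are rejected and
    logged; more than 1% rejections is an error.
    """
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100")
    central = engine_call(None)
    keys = list(central.reic)
    reic_draws = {k: [] for k in keys}
    reid_draws = {k: [] for k in keys}
    rejected = 0
    for trial in range(n_trials):
        bundle = sample_parameters(pdfs, trial)
        result = engine_call(bundle)
        vals = [result.reic[k] for k in keys] + [result.reid[k] for k in keys]
        if not np.all(np.isfinite(vals)):
            rejected += 1
            continue
        for k in keys:
            reic_draws[k].append(result.reic[k])
            reid_draws[k].append(result.reid[k])
    if rejected:
        logger.warning("rejected %d non-finite MC trials", rejected)
    if rejected > 0.01 * n_trials:
        raise RuntimeError(f"{rejected}/{n_trials} MC trials non-finite")
    qs = list(percentiles)
    reic_iv = {k: tuple(np.percentile(reic_draws[k], qs)) for k in keys}
    reid_iv = {k: tuple(np.percentile(reid_draws[k], qs)) for k in keys}
    provenance = dict(central.provenance)
    provenance.update(
        {"mc_trials": n_trials, "mc_seed": pdfs.master_seed, "mc_percentiles": qs,
         "mc_rejected": rejected}
    )
    return replace(
        central, reic_interval=reic_iv, reid_interval=reid_iv, provenance=provenance
    )
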