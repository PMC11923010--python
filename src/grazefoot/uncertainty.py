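"""Monte Carlo uncertainty propagation and the C-input sensitivity analysis.

Emission-factor uncertainty is propagated by re-pricing the deterministic
physical state (gross energy, volatile solids, excreted and applied N,
input masses) under factors sampled from per-parameter distributions:
lognormal for multiplicative factors (EF1, MCF, Ym, B0, upstream factors),
with means at the deterministic defaults so degenerate (point) specs
collapse exactly onto the deterministic footprint.  The soil carbon flux
is held at its deterministic value within the Monte Carlo and explored
separately through a +/-20% sensitivity analysis of the plant carbon
inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from grazefoot.footprint_assembly import allocate_land_burdens, intensity_and_hotspots
from grazefoot.pipeline import ModelBundle, PhysicalState, assemble_ledger, prepare_state, run_soil

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "MCSummary",
    "MCResult",
    "default_distribution_specs",
    "monte_carlo",
    "summarize",
    "cv_from_summary",
    "c_input_sensitivity",
    "sensitivity_rate_change_pct",
    "scenario_delta_pct",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling spec for one parameter.

    ``path`` addresses the parameter: ``ef.<key>`` (EF-table entry),
    ``mcf.<system>``, ``ef3.<system>``, ``ym`` or ``b0``.  Families:
    point, normal (sd), lognormal (cv), uniform (low, high), triangular
    (low, mode, high).  Samples are truncated to [lower, upper].
    """

    path: str
    family: str
    params: dict = field(default_factory=dict)
    lower: float = 0.0
    upper: float = math.inf

    def sample(self, base: float, rng: np.random.Generator) -> float:
        if self.family == "point":
            return base
        if self.family == "normal":
            v = rng.normal(base, self.params["sd"])
        elif self.family == "lognormal":
            cv = self.params["cv"]
            if cv <= 0:
                return base
            sigma = math.sqrt(math.log1p(cv * cv))
            v = rng.lognormal(math.log(base) - 0.5 * sigma * sigma, sigma) \
                if base > 0 else 0.0
        elif self.family == "uniform":
            v = rng.uniform(self.params["low"], self.params["high"])
        elif self.family == "triangular":
            v = rng.triangular(self.params["low"], self.params["mode"],
                               self.params["high"])
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")
        return float(np.clip(v, self.lower, self.upper))


@dataclass(frozen=True)
class MCSummary:
    """Summary of a Monte Carlo footprint sample (kg CO2-eq/kg LWG)."""

    n: int
    mean: float
    median: float
    sd: float
    cv_pct: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a summary needs at least 2 draws")
        if not self.ci95[0] <= self.median <= self.ci95[1]:
            raise ValueError("median must lie within the central interval")


@dataclass
class MCResult:
    sample: np.ndarray
    summary: MCSummary
    deterministic: float
    n_rejected: int


#: Pedigree-style CVs for parameters whose uncertainty is assessed
#: qualitatively (data-quality scoring mapped to a quantitative CV).
PEDIGREE_CVS = {"ym": 0.10, "b0": 0.15, "mcf.solid_storage": 0.30,
                "mcf.digester": 0.30, "ef3.solid_storage": 0.50}


def default_distribution_specs(bundle: ModelBundle) -> list[DistributionSpec]:
    """Specs from the EF table's ``dist`` entries plus the pedigree CVs."""
    specs: list[DistributionSpec] = []
    for e in bundle.ef.entries():
        fam = e.dist.get("family", "point")
        if fam == "point":
            continue
        params = {k: v for k, v in e.dist.items() if k != "family"}
        specs.append(DistributionSpec(f"ef.{e.key}", fam, params))
    for path, cv in PEDIGREE_CVS.items():
        kind = path.split(".")[0]
        if kind in ("mcf", "ef3"):
            sysname = path.split(".")[1]
            if sysname not in bundle.manure.systems:
                continue
        specs.append(DistributionSpec(path, "lognormal", {"cv": cv}))
    return specs


def _apply_overrides(bundle: ModelBundle, state: PhysicalState,
                     sampled: dict[str, float]):
    """(ef, manure, energy) with sampled parameter values in place."""
    ef_over = {p[3:]: v for p, v in sampled.items() if p.startswith("ef.")}
    ef = bundle.ef.with_overrides(ef_over) if ef_over else bundle.ef
    systems = dict(bundle.manure.systems)
    touched = False
    for p, v in sampled.items():
        if p.startswith("mcf."):
            name = p[4:]
            systems[name] = dataclasses.replace(
                systems[name], mcf_pct=float(np.clip(v, 0.0, 100.0)))
            touched = True
        elif p.startswith("ef3."):
            name = p[4:]
            systems[name] = dataclasses.replace(
                systems[name], ef3_direct=float(np.clip(v, 0.0, 1.0)))
            touched = True
    manure = replace(bundle.manure, systems=systems) if touched else bundle.manure
    energy = bundle.energy
    if "ym" in sampled:
        energy = dataclasses.replace(energy, ym_pct=float(np.clip(sampled["ym"], 1e-6, 14.999)))
    if "b0" in sampled:
        energy = dataclasses.replace(energy, b0=max(sampled["b0"], 0.0))
    return ef, manure, energy


def _evaluate(bundle: ModelBundle, state: PhysicalState, ef, manure, energy) -> float:
    ledger = assemble_ledger(state, ef, manure, energy)
    allocated = allocate_land_burdens(ledger, bundle.allocation_cattle_share)
    res = intensity_and_hotspots(allocated, state.lwg_kg, bundle.gwp,
                                 allocation_share=bundle.allocation_cattle_share)
    return res.intensity


def monte_carlo(bundle: ModelBundle, rcp: str = "rcp26",
                specs: Sequence[DistributionSpec] | None = None,
                n_draws: int = 5000, seed: int = 0,
                state: PhysicalState | None = None) -> MCResult:
    """Propagate emission-factor uncertainty to the footprint intensity.

    The physical state (including the deterministic SOC flux) is computed
    once; each draw re-prices it under sampled factors.  Draws yielding a
    non-finite footprint are rejected and logged; more than 1% rejections
    raises.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if state is None:
        state = prepare_state(bundle, rcp)
    if specs is None:
        specs = default_distribution_specs(bundle)
    bases: dict[str, float] = {}
    for s in specs:
        if s.path.startswith("ef."):
            bases[s.path] = bundle.ef.value(s.path[3:])
        elif s.path.startswith("mcf."):
            bases[s.path] = bundle.manure.systems[s.path[4:]].mcf_pct
        elif s.path.startswith("ef3."):
            bases[s.path] = bundle.manure.systems[s.path[4:]].ef3_direct
        elif s.path == "ym":
            bases[s.path] = bundle.energy.ym_pct
        elif s.path == "b0":
            bases[s.path] = bundle.energy.b0
        else:
            raise KeyError(f"unresolvable parameter path {s.path!r}")
    deterministic = _evaluate(bundle, state, bundle.ef, bundle.manure, bundle.energy)

    rng = np.random.default_rng(seed)
    values: list[float] = []
    rejected = 0
    for _ in range(n_draws):
        sampled = {s.path: s.sample(bases[s.path], rng) for s in specs}
        ef, manure, energy = _apply_overrides(bundle, state, sampled)
        v = _evaluate(bundle, state, ef, manure, energy)
        if not math.isfinite(v):
            rejected += 1
            logger.warning("rejected non-finite footprint draw")
            continue
        values.append(v)
    if rejected > 0.01 * n_draws:
        raise RuntimeError(f"{rejected}/{n_draws} Monte Carlo draws rejected")
    sample = np.asarray(values)
    return MCResult(sample=sample, summary=summarize(sample),
                    deterministic=deterministic, n_rejected=rejected)


def summarize(sample: np.ndarray) -> MCSummary:
    """Sample statistics (SD with n-1 denominator, empirical 95% interval)."""
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    mean = float(sample.mean())
    # a constant sample has SD exactly 0 (guard against the 1-ulp error of
    # deviations taken around a rounded mean)
    sd = 0.0 if sample.max() == sample.min() else float(sample.std(ddof=1))
    lo, hi = (float(v) for v in np.percentile(sample, [2.5, 97.5]))
    return MCSummary(n=n, mean=mean, median=float(np.median(sample)), sd=sd,
                     cv_pct=cv_from_summary(mean, sd) if mean > 0 else 0.0,
                     ci95=(lo, hi))


def cv_from_summary(mean: float, sd: float) -> float:
    """Coefficient of variation in %: 100 * SD / mean."""
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return 100.0 * sd / mean


def scenario_delta_pct(scenario_mean: float, baseline_mean: float) -> float:
    """Relative footprint change vs baseline, % (negative = reduction)."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (scenario_mean - baseline_mean) / baseline_mean


# ---------------------------------------------------------------------------
# C-input sensitivity
# ---------------------------------------------------------------------------

def c_input_sensitivity(bundle: ModelBundle, rcp: str = "rcp26",
                        delta: float = 0.2) -> pd.DataFrame:
    """SOC projections at plant C inputs scaled by 1-delta, 1, 1+delta.

    Returns one row per run with the final stock, the annual change rate,
    and the rate's relative change vs the no-change run (%).
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    rows = []
    rates = {}
    for label, scale in (("decrease", 1.0 - delta), ("no_change", 1.0),
                         ("increase", 1.0 + delta)):
        proj, _ = run_soil(bundle, rcp, c_input_scale=scale)
        rates[label] = proj.annual_change_rate
        rows.append({"change": label, "c_input_scale": scale,
                     "initial_soc": proj.initial_soc,
                     "final_soc": proj.final_soc,
                     "annual_rate": proj.annual_change_rate})
    df = pd.DataFrame(rows)
    mid = rates["no_change"]
    df["rate_change_pct"] = [
        100.0 * (r - mid) / mid if mid != 0 else float("nan")
        for r in df["annual_rate"]
    ]
    return df


def sensitivity_rate_change_pct(rate_decrease: float, rate_no_change: float,
                                rate_increase: float) -> tuple[float, float]:
    """Relative rate changes (%, decrease and increase arms) vs no change."""
    if rate_no_change == 0:
        raise ValueError("no-change rate must be non-zero")
    down = 100.0 * (rate_no_change - rate_decrease) / rate_no_change
    up = 100.0 * (rate_increase - rate_no_change) / rate_no_change
    return down, up
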