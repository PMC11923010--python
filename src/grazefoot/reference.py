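"""Published reference results for the study system.

Summary tables reported for the North Wyke Farm Platform permanent-pasture
beef finishing system: Monte Carlo footprint summaries per scenario and
climate pathway, and the soil-organic-carbon sensitivity table for the two
swards.  These are inputs for desk-level consistency checks (recomputing a
CV from its mean and SD, scenario deltas from means, sensitivity ratios
from rates) — they are never used to calibrate the simulation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PublishedMCRow", "PUBLISHED_MC", "PUBLISHED_SOC", "PublishedSOCRow"]


@dataclass(frozen=True)
class PublishedMCRow:
    """Reported footprint sample summary, kg CO2-eq/kg LWG."""

    scenario: str
    rcp: str
    mean: float
    median: float
    sd: float
    cv_pct: float


PUBLISHED_MC: tuple[PublishedMCRow, ...] = (
    PublishedMCRow("BAU", "rcp26", 15.06, 15.00, 3.10, 20.55),
    PublishedMCRow("BAU", "rcp85", 15.16, 15.05, 1.07, 7.06),
    PublishedMCRow("NI", "rcp26", 13.96, 13.89, 2.15, 15.37),
    PublishedMCRow("NI", "rcp85", 13.93, 14.0, 4.38, 31.45),
    PublishedMCRow("LD", "rcp26", 18.88, 18.74, 2.44, 12.94),
    PublishedMCRow("LD", "rcp85", 18.95, 18.82, 4.87, 25.70),
    PublishedMCRow("AD", "rcp26", 11.28, 11.17, 2.73, 24.20),
    PublishedMCRow("AD", "rcp85", 11.27, 11.20, 1.61, 14.26),
    PublishedMCRow("WC", "rcp26", 13.29, 13.14, 1.91, 14.37),
    PublishedMCRow("WC", "rcp85", 13.35, 13.29, 1.02, 7.60),
)


@dataclass(frozen=True)
class PublishedSOCRow:
    """Reported 100-yr SOC outcome for one sward, pathway and C-input arm."""

    sward: str          # "permanent_pasture" | "grass_clover"
    rcp: str
    c_input: str        # "decrease" | "no_change" | "increase"
    initial_soc: float  # Mg C/ha
    final_soc: float
    annual_rate: float  # Mg C/ha/yr


PUBLISHED_SOC: tuple[PublishedSOCRow, ...] = (
    PublishedSOCRow("permanent_pasture", "rcp26", "decrease", 53.78, 65.91, 0.25),
    PublishedSOCRow("permanent_pasture", "rcp26", "no_change", 53.78, 71.27, 0.31),
    PublishedSOCRow("permanent_pasture", "rcp26", "increase", 53.78, 76.63, 0.37),
    PublishedSOCRow("permanent_pasture", "rcp85", "decrease", 53.78, 63.39, 0.22),
    PublishedSOCRow("permanent_pasture", "rcp85", "no_change", 53.78, 68.47, 0.28),
    PublishedSOCRow("permanent_pasture", "rcp85", "increase", 53.78, 73.56, 0.34),
    PublishedSOCRow("grass_clover", "rcp26", "decrease", 38.88, 64.22, 0.28),
    PublishedSOCRow("grass_clover", "rcp26", "no_change", 38.88, 68.98, 0.33),
    PublishedSOCRow("grass_clover", "rcp26", "increase", 38.88, 73.74, 0.38),
    PublishedSOCRow("grass_clover", "rcp85", "decrease", 38.88, 61.77, 0.25),
    PublishedSOCRow("grass_clover", "rcp85", "no_change", 38.88, 66.30, 0.30),
    PublishedSOCRow("grass_clover", "rcp85", "increase", 38.88, 70.82, 0.35),
)


def published_mc_row(scenario: str, rcp: str) -> PublishedMCRow:
    for r in PUBLISHED_MC:
        if r.scenario == scenario and r.rcp == rcp:
            return r
    raise KeyError(f"no published row for {scenario}/{rcp}")


def published_soc_rates(sward: str, rcp: str) -> tuple[float, float, float]:
    """(decrease, no_change, increase) annual SOC change rates."""
    rows = {r.c_input: r.annual_rate for r in PUBLISHED_SOC
            if r.sward == sward and r.rcp == rcp}
    if len(rows) != 3:
        raise KeyError(f"no published rates for {sward}/{rcp}")
    return rows["decrease"], rows["no_change"], rows["increase"]
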