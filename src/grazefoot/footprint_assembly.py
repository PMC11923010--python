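"""Emission ledger, GWP100 characterisation, allocation, and intensity.

The ledger is an additive list of (source, gas, mass) entries.  Gases are
characterised with AR6 GWP100 factors (fossil CH4 29.8, biogenic CH4 27.2,
N2O 273); upstream entries supplied directly in CO2-eq use the pass-through
gas ``CO2e``.  The soil-organic-carbon flux is the only entry allowed to be
negative (a sink).  Burdens on the shared grassland (soil N2O, lime, the
fertiliser chain, the SOC flux) are split between the cattle and the sheep
enterprise by economic allocation before the footprint is normalised to
the functional unit, 1 kg of liveweight gain (LWG) at the farmgate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EmissionEntry",
    "EmissionInventory",
    "GWPFactors",
    "FootprintResult",
    "LAND_BASED_SOURCES",
    "characterize",
    "allocate_land_burdens",
    "soc_flux_entry",
    "intensity_and_hotspots",
]

C_TO_CO2 = 44.0 / 12.0

#: Source labels whose burdens arise from the shared land and are subject
#: to the cattle/sheep economic allocation.  Animal-specific sources
#: (enteric, manure management, purchased feed and bedding) are not.
LAND_BASED_SOURCES: frozenset[str] = frozenset({
    "soil_N2O", "lime", "SOC_change",
    "upstream_fert_n", "upstream_fert_p", "upstream_fert_k",
    "upstream_lime", "upstream_seed", "upstream_dcd",
    "upstream_transport_fertiliser_road",
})


@dataclass(frozen=True)
class GWPFactors:
    """AR6 100-year characterisation factors, kg CO2-eq per kg of gas."""

    co2_fossil: float = 1.0
    ch4_fossil: float = 29.8
    ch4_biogenic: float = 27.2
    n2o: float = 273.0

    def as_mapping(self) -> dict[str, float]:
        return {
            "CO2_fossil": self.co2_fossil,
            "CH4_fossil": self.ch4_fossil,
            "CH4_biogenic": self.ch4_biogenic,
            "N2O": self.n2o,
            # CO2 released from / stored in soil organic matter, and
            # upstream lines already expressed in CO2-eq
            "CO2_biogenic": 1.0,
            "CO2e": 1.0,
        }


@dataclass(frozen=True)
class EmissionEntry:
    source: str
    gas: str
    mass_kg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass_kg):
            raise ValueError("entry mass must be finite")
        if self.mass_kg < 0 and self.source != "SOC_change":
            raise ValueError(
                f"negative mass only permitted for the SOC sink, got "
                f"{self.mass_kg} for {self.source!r}")


@dataclass
class EmissionInventory:
    """Additive emission ledger."""

    entries: list[EmissionEntry] = field(default_factory=list)

    def add(self, source: str, gas: str, mass_kg: float) -> None:
        self.entries.append(EmissionEntry(source, gas, mass_kg))

    def extend(self, entries: Iterable[EmissionEntry]) -> None:
        for e in entries:
            self.entries.append(e)

    def by_source(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.entries:
            out[e.source] = out.get(e.source, 0.0) + e.mass_kg
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": e.source, "gas": e.gas, "kg": e.mass_kg}
             for e in self.entries], columns=["source", "gas", "kg"])


@dataclass(frozen=True)
class FootprintResult:
    """Characterised, allocated footprint of the finishing enterprise."""

    total_kgco2e: float           # net, sink included
    gross_kgco2e: float           # positive sources only
    intensity: float              # kg CO2-eq per kg LWG
    lwg_kg: float
    shares_pct: dict[str, float]  # % of gross, by source group
    sink_offset_pct: float        # SOC sink as % of gross
    allocation_share: float


def characterize(inventory: EmissionInventory,
                 factors: GWPFactors | None = None) -> pd.DataFrame:
    """Per-entry CO2-eq: mass x gas factor.  Unknown gases raise."""
    factors = factors or GWPFactors()
    table = factors.as_mapping()
    rows = []
    for e in inventory.entries:
        if e.gas not in table:
            raise KeyError(f"no GWP factor for gas {e.gas!r}")
        rows.append({"source": e.source, "gas": e.gas, "kg": e.mass_kg,
                     "kgco2e": e.mass_kg * table[e.gas]})
    return pd.DataFrame(rows, columns=["source", "gas", "kg", "kgco2e"])


def allocate_land_burdens(inventory: EmissionInventory, cattle_share: float,
                          land_sources: frozenset[str] = LAND_BASED_SOURCES,
                          ) -> EmissionInventory:
    """Scale land-based entries by the cattle share; leave animal-specific
    entries untouched."""
    if not 0.0 <= cattle_share <= 1.0:
        raise ValueError("allocation share must lie in [0, 1]")
    out = EmissionInventory()
    for e in inventory.entries:
        if e.source in land_sources:
            out.entries.append(replace(e, mass_kg=e.mass_kg * cattle_share))
        else:
            out.entries.append(e)
    return out


def soc_flux_entry(annual_change_rate: float, area_ha: float,
                   assessment_years: float = 1.0) -> EmissionEntry:
    """SOC change as a CO2 flux entry over the assessment period.

    A positive change rate (sequestration, Mg C/ha/yr) becomes a negative
    emission: -rate * area * 44/12 * 1000 kg CO2 per year.
    """
    if not math.isfinite(annual_change_rate):
        raise ValueError("change rate must be finite")
    mass = -annual_change_rate * area_ha * C_TO_CO2 * 1000.0 * assessment_years
    return EmissionEntry("SOC_change", "CO2_biogenic", mass)


def intensity_and_hotspots(inventory: EmissionInventory, lwg_kg: float,
                           factors: GWPFactors | None = None,
                           allocation_share: float = 1.0) -> FootprintResult:
    """Characterise a (typically already allocated) ledger and normalise.

    Shares are percentages of the gross (sink-exclusive) CO2-eq by source;
    the SOC sink is reported separately as a percentage offset of gross.
    """
    if lwg_kg <= 0:
        raise ValueError("liveweight gain must be positive")
    char = characterize(inventory, factors)
    by_source = char.groupby("source")["kgco2e"].sum()
    gross = float(by_source[by_source > 0].sum())
    sink = float(-by_source[by_source < 0].sum())
    total = float(by_source.sum())
    shares = {s: 100.0 * v / gross for s, v in by_source.items() if v > 0}
    return FootprintResult(
        total_kgco2e=total, gross_kgco2e=gross, intensity=total / lwg_kg,
        lwg_kg=lwg_kg, shares_pct=shares,
        sink_offset_pct=100.0 * sink / gross if gross > 0 else 0.0,
        allocation_share=allocation_share)
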