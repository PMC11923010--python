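"""Field-level N2O and CO2, and upstream (off-farm) emissions.

Soil N2O covers synthetic fertiliser N (with an optional nitrification-
inhibitor emission factor), organic amendments (FYM or digestate) and
excreta deposited at grazing, each with direct and indirect (volatilised
and leached N) pathways.  Liming CO2 is the carbonate carbon released on
application.  Upstream emissions price every purchased input of the farm
inventory with entries from a packaged, citable emission-factor table that
replaces proprietary LCI databases; every factor is overridable.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from grazefoot.footprint_assembly import C_TO_CO2, EmissionEntry
from grazefoot.herd_emissions import N2O_PER_N
from grazefoot.synthetic_farm import FarmInventory

logger = logging.getLogger(__name__)

__all__ = [
    "EFEntry",
    "EFTable",
    "FieldNFlows",
    "load_ef_table",
    "soil_n2o",
    "liming_co2",
    "upstream_emissions",
]


@dataclass(frozen=True)
class EFEntry:
    """One emission factor with units, gas, uncertainty spec and citation."""

    key: str
    value: float
    units: str
    gas: str
    dist: Mapping[str, Any]
    cite: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"EF {self.key!r} must be non-negative")
        if not self.cite:
            raise ValueError(f"EF {self.key!r} lacks a citation note")


class EFTable:
    """Keyed emission-factor registry."""

    def __init__(self, entries: Mapping[str, EFEntry]):
        self._entries = dict(entries)

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def __getitem__(self, key: str) -> EFEntry:
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(f"no emission factor named {key!r} in the EF table") from None

    def value(self, key: str) -> float:
        return self[key].value

    def keys(self):
        return self._entries.keys()

    def entries(self):
        return self._entries.values()

    def with_overrides(self, overrides: Mapping[str, float]) -> "EFTable":
        """Copy with some values replaced (used by scenarios and Monte Carlo)."""
        new = copy.deepcopy(self._entries)
        for key, value in overrides.items():
            if key not in new:
                raise KeyError(f"override refers to unknown EF {key!r}")
            e = new[key]
            new[key] = EFEntry(e.key, float(value), e.units, e.gas, e.dist, e.cite)
        return EFTable(new)


def load_ef_table(path: str | None = None) -> EFTable:
    """Load the packaged EF table, or a user-supplied YAML override file."""
    if path is None:
        ref = importlib.resources.files("grazefoot.data") / "ef_table.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    entries = {
        key: EFEntry(key=key, value=float(spec["value"]), units=spec["units"],
                     gas=spec.get("gas", "CO2e"), dist=spec.get("dist", {"family": "point"}),
                     cite=spec.get("cite", ""))
        for key, spec in raw.items()
    }
    return EFTable(entries)


# ---------------------------------------------------------------------------
# soil N2O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldNFlows:
    """Annual nitrogen flows to the grassland soil, kg N/yr."""

    fert_n_kg: float = 0.0
    organic_n_kg: float = 0.0      # FYM or digestate applied
    excreta_n_kg: float = 0.0      # deposited at grazing
    dcd_kg: float = 0.0            # inhibitor mass applied (for the inventory)

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.fert_n_kg, self.organic_n_kg,
                               self.excreta_n_kg, self.dcd_kg)):
            raise ValueError("N flows must be non-negative")


def soil_n2o(flows: FieldNFlows, ef: EFTable,
             inhibitor_active: bool = False,
             ef3_excreta: float | None = None,
             frac_gas_excreta: float | None = None,
             frac_leach_excreta: float | None = None,
             ) -> dict[str, dict[str, float]]:
    """Direct and indirect soil N2O (kg N2O) by N source.

    ``inhibitor_active`` swaps the synthetic-fertiliser EF1 for the
    DCD-treated value and leaves organic and excreta EFs untouched.
    Excreta deposited at grazing uses EF3(PRP)-style coefficients, passed
    in (they live with the manure-system config) or defaulting to the
    organic-amendment entries.
    """
    if inhibitor_active and flows.dcd_kg <= 0:
        logger.warning("inhibitor flagged active but no DCD mass recorded")
    ef1_f = ef.value("ef1_synthetic_dcd" if inhibitor_active else "ef1_synthetic")
    ef1_o = ef.value("ef1_organic")
    ef3_e = ef.value("ef1_organic") if ef3_excreta is None else ef3_excreta
    ef4 = ef.value("ef4_deposition")
    ef5 = ef.value("ef5_leaching")
    fgf = ef.value("frac_gasf")
    fgm = ef.value("frac_gasm")
    fl = ef.value("frac_leach")
    fge = fgm if frac_gas_excreta is None else frac_gas_excreta
    fle = fl if frac_leach_excreta is None else frac_leach_excreta

    def _one(n: float, ef1: float, fgas: float, fleach: float) -> dict[str, float]:
        return {
            "direct": n * ef1 * N2O_PER_N,
            "indirect": (n * fgas * ef4 + n * fleach * ef5) * N2O_PER_N,
        }

    return {
        "fertiliser": _one(flows.fert_n_kg, ef1_f, fgf, fl),
        "organic": _one(flows.organic_n_kg, ef1_o, fgm, fl),
        "excreta": _one(flows.excreta_n_kg, ef3_e, fge, fle),
    }


def liming_co2(lime_mass_kg: float, ef: EFTable) -> float:
    """CO2 (kg, fossil) from dissolution of applied limestone."""
    if lime_mass_kg < 0:
        raise ValueError("lime mass must be non-negative")
    return lime_mass_kg * ef.value("lime_c_fraction") * C_TO_CO2


# ---------------------------------------------------------------------------
# upstream
# ---------------------------------------------------------------------------

def upstream_quantities(inventory: FarmInventory,
                        ad_chain: bool = False) -> list[tuple[str, str, float]]:
    """(ledger source, EF key, quantity) for every non-zero inventory line."""
    lines: list[tuple[str, str, float]] = [
        ("upstream_fert_n", "upstream_fert_n", inventory.fert_n),
        ("upstream_fert_p", "upstream_fert_p", inventory.fert_p),
        ("upstream_fert_k", "upstream_fert_k", inventory.fert_k),
        ("upstream_lime", "upstream_lime", inventory.lime),
        ("upstream_rapeseed_meal", "upstream_rapeseed_meal", inventory.rapeseed_meal),
        ("upstream_straw", "upstream_straw", inventory.straw),
        ("upstream_seed", "upstream_seed", inventory.seed_kg),
        ("upstream_dcd", "upstream_dcd", inventory.dcd_kg),
    ]
    for commodity, tkm in inventory.transport_tkm.items():
        lines.append((f"upstream_transport_{commodity}", "upstream_transport_road", tkm))
    if ad_chain:
        lines.append(("upstream_ad_chain", "upstream_ad_chain", 1.0))
    return [(src, key, qty) for src, key, qty in lines if qty > 0]


def upstream_emissions(inventory: FarmInventory, ef: EFTable,
                       ad_chain: bool = False,
                       ad_allocation_to_system: float = 1.0,
                       ) -> list[EmissionEntry]:
    """Price every inventory line: emission = quantity x EF.

    ``ad_allocation_to_system`` scales only the AD-chain line (the
    digestate share of the digester's co-product allocation).
    """
    out: list[EmissionEntry] = []
    for src, key, qty in upstream_quantities(inventory, ad_chain=ad_chain):
        if key not in ef:
            raise KeyError(f"inventory line {src!r} has no EF entry {key!r}")
        entry = ef[key]
        mass = qty * entry.value
        if src == "upstream_ad_chain":
            mass *= ad_allocation_to_system
        out.append(EmissionEntry(src, entry.gas, mass))
    return out
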