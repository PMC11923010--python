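"""End-to-end assembly: synthetic farm -> ledger -> footprint.

``build_baseline_bundle`` constructs the business-as-usual model bundle
from the synthetic generators; ``run_footprint`` executes the full chain
for a bundle under one climate pathway: Tier 2 herd emissions, equilibrium
inversion of plant carbon inputs, the SOC projection, field and upstream
emissions, characterisation, economic allocation and the intensity per kg
liveweight gain.

The physical quantities (gross energy, volatile solids, excreted N, input
masses) are separated from their pricing with emission factors so the
Monte Carlo layer can re-price the same physical state under sampled
factors without re-running the herd or soil models.
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from grazefoot.field_and_upstream import (
    EFTable, FieldNFlows, liming_co2, load_ef_table, soil_n2o,
    upstream_emissions,
)
from grazefoot.footprint_assembly import (
    EmissionInventory, FootprintResult, GWPFactors, allocate_land_burdens,
    intensity_and_hotspots, soc_flux_entry,
)
from grazefoot.herd_emissions import (
    EnergyParams, GE_PER_KG_CH4, ManureSystemShares, default_manure_systems,
    forage_calendar, herd_period_emissions, manure_ch4, manure_n2o,
)
from grazefoot.rothc_soil import (
    CarbonPools, PlantInputSchedule, RothCParams, SOCProjection, init_pools,
    partition_plant_inputs, run_projection, spin_to_equilibrium,
)
from grazefoot.synthetic_farm import (
    AnimalRecord, DEVON_NORMALS, FarmInventory, ForageMonth, WeatherMonth,
    default_inventory, generate_forage_series, generate_herd, generate_weather,
)

__all__ = [
    "ModelBundle",
    "PhysicalState",
    "build_baseline_bundle",
    "prepare_state",
    "assemble_ledger",
    "run_footprint",
    "run_soil",
    "FootprintRun",
]

#: Carbon fraction of manure volatile solids / bedding organic matter.
VS_C_FRACTION = 0.5
#: Organic-matter fraction of straw dry matter entering the midden.
STRAW_VS_FRACTION = 0.85
#: Months of FYM (or digestate) field application, after winter storage.
FYM_APPLICATION_MONTHS = (3, 4)


@dataclass
class ModelBundle:
    """Everything needed to run one scenario: data plus configuration.

    Scenario transforms deep-copy a bundle and change fields; the
    ``overrides`` list records every change with a provenance note.
    """

    scenario_id: str
    inventory: FarmInventory
    herd: list[AnimalRecord]
    forage_series: list[ForageMonth]
    baseline_climate_year: list[WeatherMonth]
    weather_by_rcp: dict[str, list[WeatherMonth]]
    energy: EnergyParams
    manure: ManureSystemShares
    ef: EFTable
    soil_params: RothCParams
    initial_soc: float
    baseline_fym_c_monthly: tuple[float, ...]  # Mg C/ha, frozen at build time
    housed_system: str = "solid_storage"
    herd_scale: float = 1.0
    stocking_lu_per_ha: float = 1.04
    fym_c_retention: float = 1.0        # digestate C : FYM C under AD
    organic_n_retention: float = 1.0    # digestate N : excreted housed N under AD
    inhibitor_active: bool = False
    ad_chain: bool = False
    ad_allocation_to_system: float = 1.0  # digestate share of AD-chain burdens
    allocation_cattle_share: float = 0.74
    soc_rate_window_years: float = 100.0
    gwp: GWPFactors = field(default_factory=GWPFactors)
    overrides: list[dict] = field(default_factory=list)

    def log_override(self, path: str, old, new, note: str) -> None:
        if not note:
            raise ValueError("every override needs a provenance note")
        self.overrides.append({"path": path, "old": old, "new": new, "note": note})


@dataclass
class PhysicalState:
    """Emission-factor-free physical quantities of one scenario run."""

    ge_mj: float
    lwg_kg: float
    vs_by_system: dict[str, float]
    n_by_system: dict[str, float]
    fert_n_kg: float
    organic_n_applied_kg: float
    dcd_kg: float
    lime_kg: float
    inventory: FarmInventory
    area_ha: float
    soc_rate: float                  # Mg C/ha/yr, deterministic
    inhibitor_active: bool
    housed_system: str
    ad_chain: bool
    ad_allocation_to_system: float
    soc_projection: SOCProjection | None = None
    plant_schedule: PlantInputSchedule | None = None


def build_baseline_bundle(seed: int = 1,
                          n_animals: int = 30,
                          start_year: int = 2016,
                          horizon_year: int = 2100,
                          climate_noise: bool = False) -> ModelBundle:
    """Construct the business-as-usual bundle from the synthetic generators.

    ``climate_noise=False`` keeps the weather at the seasonal normals plus
    the warming ramp, which makes the soil projections deterministic given
    the seed-generated herd and forage data.
    """
    rng = np.random.default_rng(seed)
    herd_seed, forage_seed, w26_seed, w85_seed = rng.integers(0, 2**31 - 1, 4)
    inventory = default_inventory()
    herd = generate_herd(n_animals=n_animals, seed=int(herd_seed))
    forage = generate_forage_series(n_months=12, noise_sd=0.0, seed=int(forage_seed))
    n_years = horizon_year - start_year + 1
    noise = dict(noise_sd_temp=0.6, noise_cv_rain=0.15) if climate_noise \
        else dict(noise_sd_temp=0.0, noise_cv_rain=0.0)
    weather = {
        "rcp26": generate_weather(start_year, n_years, "rcp26_like",
                                  seed=int(w26_seed), **noise),
        "rcp85": generate_weather(start_year, n_years, "rcp85_like",
                                  seed=int(w85_seed), **noise),
    }
    baseline_year = generate_weather(start_year - 1, 1, "flat",
                                     noise_sd_temp=0.0, noise_cv_rain=0.0, seed=0)
    energy = EnergyParams()
    manure = ManureSystemShares(systems=default_manure_systems())
    ef = load_ef_table()
    soil_params = RothCParams(clay=inventory.clay_content)

    bundle = ModelBundle(
        scenario_id="BAU", inventory=inventory, herd=herd,
        forage_series=forage, baseline_climate_year=baseline_year,
        weather_by_rcp=weather, energy=energy, manure=manure, ef=ef,
        soil_params=soil_params, initial_soc=inventory.initial_soc,
        baseline_fym_c_monthly=(0.0,) * 12,
    )
    # freeze the baseline organic-amendment C schedule from the baseline herd
    totals = _herd_totals(bundle)
    bundle.baseline_fym_c_monthly = _fym_c_monthly(
        totals.vs_kg.get("solid_storage", 0.0) + totals.vs_kg.get("digester", 0.0),
        inventory.straw, inventory.farm_area)
    return bundle


def _herd_totals(bundle: ModelBundle):
    forage = forage_calendar(bundle.forage_series)
    routing = {"housed": {bundle.housed_system: 1.0},
               "pasture": {"pasture": 1.0}}
    shares = ManureSystemShares(systems=bundle.manure.systems, routing=routing)
    _, totals = herd_period_emissions(
        bundle.herd, forage, bundle.energy, shares,
        ef4=bundle.ef.value("ef4_deposition"),
        ef5=bundle.ef.value("ef5_leaching"))
    return totals


def _fym_c_monthly(vs_housed_kg: float, straw_kg: float,
                   area_ha: float) -> tuple[float, ...]:
    """Monthly FYM carbon to soil, Mg C/ha: excreta VS plus straw bedding,
    spread over the spring application window."""
    total_c_mg = VS_C_FRACTION * (vs_housed_kg + STRAW_VS_FRACTION * straw_kg) / 1000.0
    per_ha = total_c_mg / area_ha
    months = [0.0] * 12
    for m in FYM_APPLICATION_MONTHS:
        months[m - 1] = per_ha / len(FYM_APPLICATION_MONTHS)
    return tuple(months)


def _ndf_by_month(bundle: ModelBundle) -> list[float]:
    """Pasture NDF climatology (the litter-quality proxy)."""
    table = {f.month: f.ndf_pct for f in bundle.forage_series if f.source == "pasture"}
    return [table[m] for m in range(1, 13)]


def run_soil(bundle: ModelBundle, rcp: str,
             c_input_scale: float = 1.0) -> tuple[SOCProjection, PlantInputSchedule]:
    """Equilibrium inversion plus the SOC projection for one pathway.

    The inversion always uses the bundle's *baseline* organic-amendment
    schedule (the plant input is a property of the baseline field); the
    projection applies the scenario's actual amendments.
    """
    params = bundle.soil_params
    ndf = _ndf_by_month(bundle)
    dpm_frac = tuple(1.0 - v / 100.0 for v in ndf)
    schedule0 = PlantInputSchedule(plant_c=(1.0 / 12,) * 12,
                                   dpm_fraction=dpm_frac,
                                   fym_c=bundle.baseline_fym_c_monthly)
    annual_input = spin_to_equilibrium(
        bundle.initial_soc, params.clay, bundle.baseline_climate_year,
        schedule0, params)
    totals = _herd_totals(bundle)
    vs_housed = (totals.vs_kg.get("solid_storage", 0.0)
                 + totals.vs_kg.get("digester", 0.0))
    # the whole FYM stream (excreta plus straw bedding) is herd-proportional
    fym_actual = _fym_c_monthly(vs_housed, bundle.inventory.straw,
                                bundle.inventory.farm_area)
    fym_actual = tuple(v * bundle.herd_scale * bundle.fym_c_retention
                       for v in fym_actual)
    schedule, _ = partition_plant_inputs(
        bundle.inventory.yield_dm, annual_input * c_input_scale, ndf,
        fym_c_by_month=fym_actual)
    pools0 = init_pools(bundle.initial_soc, params.clay)
    proj = run_projection(pools0, schedule, bundle.weather_by_rcp[rcp], params,
                          rate_window_years=bundle.soc_rate_window_years)
    return proj, schedule


def prepare_state(bundle: ModelBundle, rcp: str,
                  c_input_scale: float = 1.0) -> PhysicalState:
    """Run the physical models once; the result can be re-priced under
    different emission factors (the Monte Carlo fast path)."""
    totals = _herd_totals(bundle)
    s = bundle.herd_scale
    vs = {k: v * s for k, v in totals.vs_kg.items()}
    n = {k: v * s for k, v in totals.n_ex_kg.items()}
    housed_sys = bundle.manure.systems[bundle.housed_system]
    n_housed = n.get(bundle.housed_system, 0.0)
    organic_n = n_housed * (1.0 - housed_sys.frac_gas - housed_sys.frac_leach) \
        * bundle.organic_n_retention
    proj, schedule = run_soil(bundle, rcp, c_input_scale)
    return PhysicalState(
        ge_mj=totals.ge_mj * s, lwg_kg=totals.lwg_kg * s,
        vs_by_system=vs, n_by_system=n,
        fert_n_kg=bundle.inventory.fert_n,
        organic_n_applied_kg=organic_n,
        dcd_kg=bundle.inventory.dcd_kg,
        lime_kg=bundle.inventory.lime,
        inventory=bundle.inventory, area_ha=bundle.inventory.farm_area,
        soc_rate=proj.annual_change_rate,
        inhibitor_active=bundle.inhibitor_active,
        housed_system=bundle.housed_system,
        ad_chain=bundle.ad_chain,
        ad_allocation_to_system=bundle.ad_allocation_to_system,
        soc_projection=proj, plant_schedule=schedule)


def assemble_ledger(state: PhysicalState, ef: EFTable,
                    manure: ManureSystemShares,
                    energy: EnergyParams) -> EmissionInventory:
    """Price the physical state into the emission ledger.

    Source conventions: the manure-management source covers the housed
    storage chain only (midden or digester); excreta deposited at grazing
    — its N2O and its small CH4 — are field emissions booked under the
    soil source, which is what the anaerobic-digestion scenario (applied
    to housed FYM only) leaves untouched.
    """
    inv = EmissionInventory()
    # enteric fermentation
    inv.add("enteric", "CH4_biogenic",
            state.ge_mj * (energy.ym_pct / 100.0) / GE_PER_KG_CH4)
    # manure management: housed storage chain
    ef4, ef5 = ef.value("ef4_deposition"), ef.value("ef5_leaching")
    storage = {state.housed_system: state.vs_by_system.get(state.housed_system, 0.0)}
    mm_alloc = state.ad_allocation_to_system if state.ad_chain else 1.0
    ch4 = manure_ch4(storage, manure.systems, energy.b0, energy.methane_density)
    n_storage = {state.housed_system: state.n_by_system.get(state.housed_system, 0.0)}
    n2o_d, n2o_i = manure_n2o(n_storage, manure.systems, ef4, ef5)
    inv.add("manure_management", "CH4_biogenic", sum(ch4.values()) * mm_alloc)
    inv.add("manure_management", "N2O",
            (sum(n2o_d.values()) + sum(n2o_i.values())) * mm_alloc)
    # excreta at grazing: field emissions
    past = manure.systems["pasture"]
    vs_past = state.vs_by_system.get("pasture", 0.0)
    n_past = state.n_by_system.get("pasture", 0.0)
    inv.add("soil_N2O", "CH4_biogenic",
            manure_ch4({"pasture": vs_past}, manure.systems, energy.b0,
                       energy.methane_density)["pasture"])
    flows = FieldNFlows(fert_n_kg=state.fert_n_kg,
                        organic_n_kg=state.organic_n_applied_kg,
                        excreta_n_kg=n_past, dcd_kg=state.dcd_kg)
    n2o = soil_n2o(flows, ef, inhibitor_active=state.inhibitor_active,
                   ef3_excreta=past.ef3_direct,
                   frac_gas_excreta=past.frac_gas,
                   frac_leach_excreta=past.frac_leach)
    for src in ("fertiliser", "organic", "excreta"):
        inv.add("soil_N2O", "N2O", n2o[src]["direct"] + n2o[src]["indirect"])
    # liming and upstream
    inv.add("lime", "CO2_fossil", liming_co2(state.lime_kg, ef))
    inv.extend(upstream_emissions(state.inventory, ef, ad_chain=state.ad_chain,
                                  ad_allocation_to_system=state.ad_allocation_to_system))
    # soil organic carbon flux
    inv.entries.append(soc_flux_entry(state.soc_rate, state.area_ha))
    return inv


@dataclass
class FootprintRun:
    """One scenario x pathway footprint with its intermediate artefacts."""

    scenario_id: str
    rcp: str
    state: PhysicalState
    ledger: EmissionInventory          # pre-allocation
    allocated: EmissionInventory
    result: FootprintResult


def run_footprint(bundle: ModelBundle, rcp: str = "rcp26") -> FootprintRun:
    """Execute the full chain for one bundle under one climate pathway."""
    state = prepare_state(bundle, rcp)
    ledger = assemble_ledger(state, bundle.ef, bundle.manure, bundle.energy)
    allocated = allocate_land_burdens(ledger, bundle.allocation_cattle_share)
    result = intensity_and_hotspots(allocated, state.lwg_kg, bundle.gwp,
                                    allocation_share=bundle.allocation_cattle_share)
    return FootprintRun(scenario_id=bundle.scenario_id, rcp=rcp, state=state,
                        ledger=ledger, allocated=allocated, result=result)
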