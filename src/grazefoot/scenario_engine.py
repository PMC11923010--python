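"""Mitigation scenarios as pure, auditable overrides of the baseline.

Each transform deep-copies the baseline bundle, changes the relevant
parameters, and logs every change with a provenance note; the baseline
object is never mutated.  Scenarios:

* ``NI`` — dicyandiamide (DCD) with the fertiliser: direct fertiliser N2O
  emission factor drops to 0.54%, DCD applied at 10 kg/ha of fertilised
  area, with its production and transport added upstream.
* ``LD`` — 50% destocking (1.04 -> 0.52 LU/ha): livestock-proportional
  emissions and the liveweight output halve, manure-derived soil inputs
  halve, plant carbon inputs and land-based lines stay at baseline.
* ``WC`` — white clover replaces fertiliser N: fertiliser lines and their
  upstream chain removed, seed added, grass-clover diet quality (DE 72.8%)
  and the clover field's initial SOC (38.88 Mg C/ha).
* ``AD`` — anaerobic digestion of housed FYM: gas-tight digester and
  sealed digestate store replace the midden, digestate (with transformed
  C and N) replaces FYM on the field, the digester chain is added upstream
  and carries a 76/24 biogas/digestate economic allocation of which only
  the digestate share stays with the beef system.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, replace

from grazefoot.pipeline import ModelBundle
from grazefoot.synthetic_farm import ForageMonth

__all__ = ["ADParams", "SCENARIO_IDS", "apply_scenario",
           "ni_transform", "ld_transform", "wc_transform", "ad_transform"]

SCENARIO_IDS = ("BAU", "NI", "LD", "WC", "AD")

#: Direct N2O emission factor for ammonium nitrate applied with DCD.
EF1_DCD = 0.0054
#: DCD application rate, kg/ha of fertilised area.
DCD_RATE_KG_HA = 10.0

#: Grass-clover sward diet quality (DE % of GE, CP % of DM, NDF % of DM).
WC_PASTURE_QUALITY = (72.8, 24.0, 43.0)
WC_SILAGE_QUALITY = (72.8, 16.5, 49.0)
#: Initial SOC of the grass-clover field, Mg C/ha.
WC_INITIAL_SOC = 38.88
#: Clover over-sowing seed rate, kg/ha.
WC_SEED_RATE_KG_HA = 10.0


@dataclass(frozen=True)
class ADParams:
    """Anaerobic digestion configuration.

    ``digestate_mass_kg`` is informational (the annual digestate return);
    the C/N transformation ratios are digestate:FYM post/pre-digestion
    coefficients; the digester's residual CH4 leakage replaces the midden
    MCF; allocation shares split the digester-chain burdens between the
    biogas (exported) and digestate (retained) co-products.
    """

    digestate_mass_kg: float = 1986.0
    c_retention: float = 0.55
    n_retention: float = 0.95
    digester_mcf_pct: float = 0.1
    biogas_share: float = 0.76
    digestate_share: float = 0.24

    def __post_init__(self) -> None:
        if abs(self.biogas_share + self.digestate_share - 1.0) > 1e-9:
            raise ValueError("biogas and digestate allocation shares must sum to 1")
        for r in (self.c_retention, self.n_retention):
            if not 0.0 < r < 2.0:
                raise ValueError("transformation ratios must lie in (0, 2)")


def apply_scenario(baseline: ModelBundle, scenario_id: str,
                   ad_params: ADParams | None = None) -> ModelBundle:
    """Return the scenario bundle; ``BAU`` returns an identical deep copy."""
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}")
    if scenario_id == "BAU":
        return copy.deepcopy(baseline)
    if scenario_id == "NI":
        return ni_transform(baseline)
    if scenario_id == "LD":
        return ld_transform(baseline)
    if scenario_id == "WC":
        return wc_transform(baseline)
    return ad_transform(baseline, ad_params or ADParams())


def ni_transform(baseline: ModelBundle) -> ModelBundle:
    b = copy.deepcopy(baseline)
    b.scenario_id = "NI"
    old_ef = b.ef.value("ef1_synthetic")
    b.ef = b.ef.with_overrides({"ef1_synthetic_dcd": EF1_DCD})
    b.inhibitor_active = True
    b.log_override("ef.ef1_synthetic (effective)", old_ef, EF1_DCD,
                   "DCD-treated ammonium nitrate direct EF1 of 0.54% from "
                   "UK/Irish grassland flux trials")
    dcd = DCD_RATE_KG_HA * b.inventory.fertilised_area
    b.inventory = replace(b.inventory, dcd_kg=dcd)
    b.log_override("inventory.dcd_kg", 0.0, dcd,
                   "DCD at the recommended 10 kg/ha over the fertilised area; "
                   "production and transport priced upstream")
    return b


def ld_transform(baseline: ModelBundle) -> ModelBundle:
    """50% destocking: livestock-proportional flows exactly halve.

    Implemented as a 0.5 multiplier on animal-derived physical quantities
    (the destocking assumption is proportionality, not a particular
    sub-herd), so enteric and manure emissions and the liveweight output
    are exactly half the baseline while plant carbon inputs and the
    land-based input lines stay unchanged.
    """
    b = copy.deepcopy(baseline)
    b.scenario_id = "LD"
    b.herd_scale = baseline.herd_scale * 0.5
    b.log_override("herd_scale", baseline.herd_scale, b.herd_scale,
                   "livestock density halved; enteric and manure flows "
                   "proportional to stock")
    b.stocking_lu_per_ha = baseline.stocking_lu_per_ha * 0.5
    b.log_override("stocking_lu_per_ha", baseline.stocking_lu_per_ha,
                   b.stocking_lu_per_ha, "0.52 instead of 1.04 LU/ha")
    return b


def wc_transform(baseline: ModelBundle) -> ModelBundle:
    b = copy.deepcopy(baseline)
    b.scenario_id = "WC"
    inv = b.inventory
    transport = dict(inv.transport_tkm)
    old_fert_tkm = transport.pop("fertiliser_road", 0.0)
    seed = WC_SEED_RATE_KG_HA * inv.farm_area
    b.inventory = replace(inv, fert_n=0.0, fert_p=0.0, fert_k=0.0,
                          transport_tkm=transport, seed_kg=seed,
                          initial_soc=WC_INITIAL_SOC)
    b.log_override("inventory.fert_n/p/k", (inv.fert_n, inv.fert_p, inv.fert_k),
                   (0.0, 0.0, 0.0),
                   "symbiotic N fixation replaces fertiliser; no production "
                   "or transport of fertilisers")
    b.log_override("inventory.transport_tkm.fertiliser_road", old_fert_tkm, 0.0,
                   "fertiliser haulage removed with the fertiliser")
    b.log_override("inventory.seed_kg", inv.seed_kg, seed,
                   "clover over-sowing seed, priced upstream")
    b.initial_soc = WC_INITIAL_SOC
    b.log_override("initial_soc", inv.initial_soc, WC_INITIAL_SOC,
                   "measured initial stock of the grass-clover field")
    b.forage_series = [
        ForageMonth(f.month, f.source,
                    *(WC_PASTURE_QUALITY if f.source == "pasture" else WC_SILAGE_QUALITY))
        for f in b.forage_series
    ]
    b.log_override("forage.de_pct", 71.7, 72.8,
                   "grass-clover mixture digestibility vs baseline sward")
    return b


def ad_transform(baseline: ModelBundle, ad: ADParams | None = None) -> ModelBundle:
    ad = ad or ADParams()
    b = copy.deepcopy(baseline)
    b.scenario_id = "AD"
    systems = dict(b.manure.systems)
    old = systems["digester"]
    systems["digester"] = dataclasses.replace(old, mcf_pct=ad.digester_mcf_pct)
    b.manure = replace(b.manure, systems=systems)
    b.housed_system = "digester"
    b.log_override("housed_system", baseline.housed_system, "digester",
                   "housed FYM routed to a gas-tight digester with sealed, "
                   "gas-capturing digestate storage; MCF is fugitive leakage only")
    b.fym_c_retention = ad.c_retention
    b.organic_n_retention = ad.n_retention
    b.log_override("fym_c_retention", baseline.fym_c_retention, ad.c_retention,
                   "digestate C per unit FYM C (post/pre digestion coefficient)")
    b.log_override("organic_n_retention", baseline.organic_n_retention,
                   ad.n_retention,
                   "digestate N per unit excreted housed N (post/pre coefficient)")
    b.ad_chain = True
    b.ad_allocation_to_system = ad.digestate_share
    b.log_override("ad_allocation_to_system", 1.0, ad.digestate_share,
                   "76/24 biogas/digestate economic allocation; only the "
                   "digestate share of digester-chain burdens stays with beef")
    return b
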