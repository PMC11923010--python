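"""IPCC Tier 2 livestock emissions, per animal and per weighing period.

The net-energy chain for growing beef cattle is evaluated between every
pair of consecutive weighing events: maintenance energy from metabolic
midpoint weight, growth energy from the period's average daily gain (ADG)
and mature weight, the ratios REM/REG from diet digestible energy (DE),
giving gross energy (GE) intake; enteric CH4 from GE and the methane
conversion factor Ym; volatile solids (VS) and excreted nitrogen from the
energy and protein balance; manure CH4 from VS, B0 and the per-system
methane conversion factor (MCF); and manure N2O (direct + indirect) from
excreted N and per-system emission factors.

Periods spanning the housing boundary (housed 1 Oct - 30 Apr) are split by
calendar month, with the silage diet and zero activity allowance while
housed and the pasture diet with a grazing activity allowance otherwise.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from grazefoot.synthetic_farm import AnimalRecord, ForageMonth, month_is_housed

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyParams",
    "ManureSystem",
    "ManureSystemShares",
    "PeriodEmission",
    "HerdTotals",
    "gross_energy_intake",
    "enteric_ch4",
    "excreta",
    "nitrogen_retention",
    "manure_ch4",
    "manure_n2o",
    "herd_period_emissions",
]

#: MJ of gross energy per kg of CH4 (IPCC energy content of methane).
GE_PER_KG_CH4 = 55.65
#: kg N2O per kg N2O-N.
N2O_PER_N = 44.0 / 28.0


@dataclass(frozen=True)
class EnergyParams:
    """Coefficients of the Tier 2 net-energy chain for growing cattle.

    ``cfi`` is the maintenance coefficient (MJ/d per kg^0.75),
    ``growth_c`` the sex coefficient of the growth-energy equation
    (0.8 females, 1.0 castrates), ``mature_weight`` the mature liveweight
    of an adult female of the breed cross.  ``ym_pct`` is the enteric
    methane conversion factor (% of GE).  Defaults follow the 2019-refined
    guideline values for non-lactating cattle on high-forage diets.
    """

    cfi: Mapping[str, float] = field(
        default_factory=lambda: {"steer": 0.322, "heifer": 0.322})
    growth_c: Mapping[str, float] = field(
        default_factory=lambda: {"steer": 1.0, "heifer": 0.8})
    mature_weight: Mapping[str, float] = field(
        default_factory=lambda: {"steer": 650.0, "heifer": 650.0})
    activity_pasture: float = 0.17   # fraction of NEm while grazing
    activity_housed: float = 0.0
    ym_pct: float = 6.5
    energy_density_feed: float = 18.45  # MJ GE per kg DM
    urinary_energy_fraction: float = 0.04
    ash_fraction: float = 0.08
    b0: float = 0.18                 # m3 CH4 / kg VS
    methane_density: float = 0.67    # kg CH4 / m3

    def __post_init__(self) -> None:
        if not 0.0 < self.ym_pct < 15.0:
            raise ValueError("Ym must lie in (0, 15) % of GE")
        positives = (self.energy_density_feed, self.b0, self.methane_density)
        if any(v <= 0 for v in positives):
            raise ValueError("energy/methane coefficients must be positive")


@dataclass(frozen=True)
class ManureSystem:
    """One manure management system and its emission coefficients.

    ``mcf_pct`` in % of B0; ``ef3_direct`` in kg N2O-N per kg N;
    ``frac_gas``/``frac_leach`` the volatilised and leached N fractions
    feeding indirect N2O.
    """

    name: str
    mcf_pct: float
    ef3_direct: float
    frac_gas: float
    frac_leach: float
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mcf_pct <= 100.0:
            raise ValueError("MCF must lie in [0, 100] %")
        for v in (self.ef3_direct, self.frac_gas, self.frac_leach):
            if not 0.0 <= v <= 1.0:
                raise ValueError("N fractions/EFs must lie in [0, 1]")


def default_manure_systems() -> dict[str, ManureSystem]:
    """Cool-temperate annual-average defaults for the three systems used."""
    return {
        "solid_storage": ManureSystem(
            "solid_storage", mcf_pct=4.0, ef3_direct=0.010,
            frac_gas=0.30, frac_leach=0.02,
            note="FYM midden under cover, ~6 months; cool temperate"),
        "pasture": ManureSystem(
            "pasture", mcf_pct=0.47, ef3_direct=0.006,
            frac_gas=0.21, frac_leach=0.24,
            note="dung and urine deposited at grazing, wet climate"),
        "digester": ManureSystem(
            "digester", mcf_pct=0.1, ef3_direct=0.0,
            frac_gas=0.0, frac_leach=0.0,
            note="gas-tight digester + sealed digestate store with gas "
                 "capture; MCF is the fugitive leakage only"),
    }


@dataclass(frozen=True)
class ManureSystemShares:
    """Routing of excreta to manure systems by animal location.

    ``routing`` maps a location ('housed' | 'pasture') to per-system
    shares that must sum to 1.
    """

    systems: Mapping[str, ManureSystem]
    routing: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"housed": {"solid_storage": 1.0},
                                 "pasture": {"pasture": 1.0}})

    def __post_init__(self) -> None:
        for loc, shares in self.routing.items():
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError(f"shares for location {loc!r} must sum to 1")
            for sys_name in shares:
                if sys_name not in self.systems:
                    raise KeyError(f"routing refers to unknown system {sys_name!r}")


@dataclass(frozen=True)
class PeriodEmission:
    """Emissions of one animal over one weighing interval."""

    animal_id: str
    start: dt.date
    end: dt.date
    days: int
    ge_mj: float
    enteric_ch4_kg: float
    manure_ch4_kg: float
    manure_n2o_direct_kg: float
    manure_n2o_indirect_kg: float
    vs_kg: float
    n_ex_kg: float


@dataclass
class HerdTotals:
    """Herd-level aggregates; the physical quantities (GE, VS, N) are the
    state the Monte Carlo layer re-prices under sampled emission factors."""

    ge_mj: float = 0.0
    enteric_ch4_kg: float = 0.0
    manure_ch4_kg: dict[str, float] = field(default_factory=dict)
    manure_n2o_direct_kg: dict[str, float] = field(default_factory=dict)
    manure_n2o_indirect_kg: dict[str, float] = field(default_factory=dict)
    vs_kg: dict[str, float] = field(default_factory=dict)
    n_ex_kg: dict[str, float] = field(default_factory=dict)
    lwg_kg: float = 0.0


# ---------------------------------------------------------------------------
# Tier 2 primitives
# ---------------------------------------------------------------------------

def _rem(de: float) -> float:
    return 1.123 - 4.092e-3 * de + 1.126e-5 * de * de - 25.4 / de

def _reg(de: float) -> float:
    return 1.164 - 5.160e-3 * de + 1.308e-5 * de * de - 37.4 / de


def net_energy_growth(mid_weight: float, adg: float, sex: str,
                      params: EnergyParams) -> float:
    """NEg (MJ/d) from the growth equation; floored at zero for weight loss."""
    if adg <= 0:
        if adg < 0:
            logger.warning("negative ADG (%.3f kg/d): NEg floored at 0", adg)
        return 0.0
    c = params.growth_c[sex]
    mw = params.mature_weight[sex]
    return 22.02 * (mid_weight / (c * mw)) ** 0.75 * adg ** 1.097


def gross_energy_intake(start_weight: float, end_weight: float, days: int,
                        diet: ForageMonth, params: EnergyParams,
                        sex: str) -> float:
    """Gross energy intake (MJ/day) over one period on one diet.

    The feeding situation follows the diet source: grazing activity
    allowance on pasture, none on silage (housed).
    """
    if start_weight <= 0 or end_weight <= 0:
        raise ValueError("weights must be positive")
    if days < 1:
        raise ValueError("period length must be >= 1 day")
    de = diet.de_pct
    if not 0.0 < de < 100.0:
        raise ValueError("DE must lie in (0, 100)")
    mid = 0.5 * (start_weight + end_weight)
    adg = (end_weight - start_weight) / days
    nem = params.cfi[sex] * mid ** 0.75
    ca = params.activity_pasture if diet.source == "pasture" else params.activity_housed
    nea = ca * nem
    neg = net_energy_growth(mid, adg, sex, params)
    ge = ((nem + nea) / _rem(de) + neg / _reg(de)) / (de / 100.0)
    return ge


def enteric_ch4(ge_mj_per_day: float, days: float, ym_pct: float) -> float:
    """Enteric CH4 (kg, biogenic): GE * Ym / 55.65."""
    if ge_mj_per_day < 0:
        raise ValueError("GE must be >= 0")
    return ge_mj_per_day * days * (ym_pct / 100.0) / GE_PER_KG_CH4


def nitrogen_retention(adg: float, neg_mj_per_day: float) -> float:
    """N retained in body tissue (kg N/day) for growing cattle."""
    if adg <= 0:
        return 0.0
    return adg * (268.0 - 7.03 * neg_mj_per_day / adg) / 1000.0 / 6.25


def excreta(ge_mj_per_day: float, diet: ForageMonth, params: EnergyParams,
            adg: float = 0.0, neg_mj_per_day: float = 0.0) -> tuple[float, float]:
    """Volatile solids and excreted N (kg/day) from the energy/protein balance.

    VS = [GE*(1 - DE/100) + UE*GE] * (1 - ash)/18.45; N excreted is intake
    (GE/18.45 * CP/6.25) minus tissue retention, clamped at zero.
    """
    de, cp = diet.de_pct, diet.cp_pct
    if not (0.0 < de < 100.0 and 0.0 < cp < 100.0):
        raise ValueError("DE and CP must lie in (0, 100)")
    vs = (ge_mj_per_day * (1.0 - de / 100.0)
          + params.urinary_energy_fraction * ge_mj_per_day) \
        * (1.0 - params.ash_fraction) / params.energy_density_feed
    n_intake = ge_mj_per_day / params.energy_density_feed * (cp / 100.0) / 6.25
    n_ret = nitrogen_retention(adg, neg_mj_per_day)
    n_ex = n_intake - n_ret
    if n_ex < 0:
        logger.warning("N retention (%.3f) exceeds intake (%.3f); clamping at 0",
                       n_ret, n_intake)
        n_ex = 0.0
    return vs, n_ex


def manure_ch4(vs_by_system: Mapping[str, float],
               systems: Mapping[str, ManureSystem],
               b0: float, methane_density: float = 0.67) -> dict[str, float]:
    """Manure CH4 (kg, biogenic) per system: VS * B0 * rho_CH4 * MCF/100."""
    out: dict[str, float] = {}
    for name, vs in vs_by_system.items():
        if name not in systems:
            raise KeyError(f"no MCF configured for manure system {name!r}")
        out[name] = vs * b0 * methane_density * systems[name].mcf_pct / 100.0
    return out


def manure_n2o(n_by_system: Mapping[str, float],
               systems: Mapping[str, ManureSystem],
               ef4: float, ef5: float) -> tuple[dict[str, float], dict[str, float]]:
    """Manure N2O (kg N2O) per system, direct and indirect.

    Direct: N * EF3 * 44/28.  Indirect: volatilised N * EF4 plus leached
    N * EF5, converted to N2O.
    """
    if not (0.0 <= ef4 <= 1.0 and 0.0 <= ef5 <= 1.0):
        raise ValueError("EF4/EF5 must lie in [0, 1]")
    direct: dict[str, float] = {}
    indirect: dict[str, float] = {}
    for name, n in n_by_system.items():
        sys = systems[name]
        direct[name] = n * sys.ef3_direct * N2O_PER_N
        indirect[name] = (n * sys.frac_gas * ef4 + n * sys.frac_leach * ef5) * N2O_PER_N
    return direct, indirect


# ---------------------------------------------------------------------------
# herd assembly
# ---------------------------------------------------------------------------

def _month_segments(start: dt.date, end: dt.date) -> Iterable[tuple[dt.date, int]]:
    """Split [start, end) into calendar-month segments of (first day, n days)."""
    cur = start
    while cur < end:
        if cur.month == 12:
            next_month = dt.date(cur.year + 1, 1, 1)
        else:
            next_month = dt.date(cur.year, cur.month + 1, 1)
        seg_end = min(next_month, end)
        yield cur, (seg_end - cur).days
        cur = seg_end


ForageLookup = Callable[[int, str], ForageMonth]


def forage_calendar(series: Iterable[ForageMonth]) -> ForageLookup:
    """Build a (month, source) -> ForageMonth lookup from a forage series.

    With multi-year series, later entries for the same calendar month win
    (the calendar is treated as a monthly climatology).
    """
    table: dict[tuple[int, str], ForageMonth] = {}
    for f in series:
        table[(f.month, f.source)] = f

    def lookup(month: int, source: str) -> ForageMonth:
        return table[(month, source)]

    return lookup


def herd_period_emissions(
    herd: Iterable[AnimalRecord],
    forage: ForageLookup,
    params: EnergyParams,
    shares: ManureSystemShares,
    ef4: float = 0.010,
    ef5: float = 0.011,
) -> tuple[list[PeriodEmission], HerdTotals]:
    """Tier 2 emissions for every animal and weighing interval.

    Each interval is split by calendar month; housed months use the silage
    diet and route excreta per the 'housed' manure shares, grazing months
    the pasture diet and 'pasture' shares.  Animals with fewer than two
    weighings are skipped with a warning.  Totals are exact sums over
    periods (additivity is an invariant, not an approximation).
    """
    periods: list[PeriodEmission] = []
    totals = HerdTotals()
    sysnames = list(shares.systems)
    for k in sysnames:
        totals.manure_ch4_kg.setdefault(k, 0.0)
        totals.manure_n2o_direct_kg.setdefault(k, 0.0)
        totals.manure_n2o_indirect_kg.setdefault(k, 0.0)
        totals.vs_kg.setdefault(k, 0.0)
        totals.n_ex_kg.setdefault(k, 0.0)

    for animal in herd:
        if len(animal.weighings) < 2:
            logger.warning("animal %s has <2 weighings; skipped", animal.id)
            continue
        totals.lwg_kg += animal.liveweight_gain
        for (d0, w0), (d1, w1) in zip(animal.weighings, animal.weighings[1:]):
            days = (d1 - d0).days
            adg = (w1 - w0) / days
            ge_p = ch4_p = vs_p = nex_p = 0.0
            vs_sys = {k: 0.0 for k in sysnames}
            n_sys = {k: 0.0 for k in sysnames}
            for seg_start, seg_days in _month_segments(d0, d1):
                housed = month_is_housed(seg_start.month)
                source = "silage" if housed else "pasture"
                diet = forage(seg_start.month, source)
                # midpoint weight of the whole period; weighing records are
                # period-resolution, sub-period weights are not observable
                ge_day = gross_energy_intake(w0, w1, days, diet, params,
                                             animal.sex)
                mid = 0.5 * (w0 + w1)
                neg = net_energy_growth(mid, adg, animal.sex, params)
                vs_day, nex_day = excreta(ge_day, diet, params, adg, neg)
                ge_p += ge_day * seg_days
                ch4_p += enteric_ch4(ge_day, seg_days, params.ym_pct)
                vs_p += vs_day * seg_days
                nex_p += nex_day * seg_days
                loc = "housed" if housed else "pasture"
                for sys_name, share in shares.routing[loc].items():
                    vs_sys[sys_name] += vs_day * seg_days * share
                    n_sys[sys_name] += nex_day * seg_days * share
            mch4 = manure_ch4(vs_sys, shares.systems, params.b0,
                              params.methane_density)
            n2o_d, n2o_i = manure_n2o(n_sys, shares.systems, ef4, ef5)
            periods.append(PeriodEmission(
                animal_id=animal.id, start=d0, end=d1, days=days,
                ge_mj=ge_p, enteric_ch4_kg=ch4_p,
                manure_ch4_kg=sum(mch4.values()),
                manure_n2o_direct_kg=sum(n2o_d.values()),
                manure_n2o_indirect_kg=sum(n2o_i.values()),
                vs_kg=vs_p, n_ex_kg=nex_p,
            ))
            totals.ge_mj += ge_p
            totals.enteric_ch4_kg += ch4_p
            for k in sysnames:
                totals.vs_kg[k] += vs_sys[k]
                totals.n_ex_kg[k] += n_sys[k]
                totals.manure_ch4_kg[k] += mch4[k]
                totals.manure_n2o_direct_kg[k] += n2o_d[k]
                totals.manure_n2o_indirect_kg[k] += n2o_i[k]
    return periods, totals
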