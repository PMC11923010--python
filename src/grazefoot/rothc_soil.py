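"""Five-pool monthly RothC soil organic carbon simulator for grassland.

State is four active pools (DPM, RPM, BIO, HUM) plus inert organic matter
(IOM), all in Mg C/ha over the topsoil (default 23 cm).  Each month every
active pool decays first-order at k*a*b*c/12 where a, b, c are the
temperature, topsoil-moisture-deficit and soil-cover rate modifiers;
decayed carbon splits between CO2 and the BIO/HUM pools by a clay
function.  Plant inputs enter as DPM/RPM by a litter-quality split proxied
by diet NDF; farmyard manure (or digestate) enters 49/49/2 into
DPM/RPM/HUM.

Initial pools come from pedotransfer functions of total SOC and clay, with
IOM following the Falloon power law 0.049 * SOC^1.139 and DPM taking the
residual.  The annual plant carbon input is recovered by inversion: under
a repeated baseline climate year the model is an affine map on the active
pools, so the input consistent with a steady state at the measured stock
solves a single linear system.  Permanent grassland is treated as covered
soil (c = 0.6) in every month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from grazefoot.synthetic_farm import WeatherMonth

__all__ = [
    "CarbonPools",
    "RothCParams",
    "PlantInputSchedule",
    "falloon_iom",
    "init_pools",
    "rate_modifiers",
    "monthly_modifiers",
    "step_month",
    "spin_to_equilibrium",
    "partition_plant_inputs",
    "run_projection",
    "SOCProjection",
]


@dataclass(frozen=True)
class CarbonPools:
    """RothC pool state, Mg C/ha."""

    dpm: float
    rpm: float
    bio: float
    hum: float
    iom: float

    def __post_init__(self) -> None:
        if any(v < -1e-12 for v in (self.dpm, self.rpm, self.bio, self.hum, self.iom)):
            raise ValueError("carbon pools must be non-negative")

    @property
    def total(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum + self.iom

    def active(self) -> np.ndarray:
        return np.array([self.dpm, self.rpm, self.bio, self.hum])


@dataclass(frozen=True)
class RothCParams:
    """Model constants; the published RothC-26.3 values by default, kept in
    config so a tailored grassland variant can override them."""

    k: tuple[float, float, float, float] = (10.0, 0.3, 0.66, 0.02)  # /yr DPM,RPM,BIO,HUM
    clay: float = 36.0
    depth_cm: float = 23.0
    covered: bool = True           # permanent pasture is never bare
    bio_fraction: float = 0.46     # BIO share of the retained decayed C
    fym_partition: tuple[float, float, float] = (0.49, 0.49, 0.02)  # DPM,RPM,HUM

    def __post_init__(self) -> None:
        if any(ki <= 0 for ki in self.k):
            raise ValueError("decay constants must be positive")
        if abs(sum(self.fym_partition) - 1.0) > 1e-9:
            raise ValueError("FYM partition must sum to 1")
        if not 0.0 < self.clay < 100.0:
            raise ValueError("clay must lie in (0, 100) %")

    @property
    def co2_ratio(self) -> float:
        """CO2 : (BIO+HUM) partition ratio x as a function of clay."""
        return 1.67 * (1.85 + 1.60 * math.exp(-0.0786 * self.clay))

    @property
    def max_smd(self) -> float:
        """Maximum topsoil moisture deficit (mm) for vegetated soil."""
        c = self.clay
        return (20.0 + 1.3 * c - 0.01 * c * c) * self.depth_cm / 23.0


@dataclass(frozen=True)
class PlantInputSchedule:
    """Monthly carbon inputs to the soil (Mg C/ha per month, Jan..Dec).

    ``dpm_fraction[m]`` is the decomposable share of that month's plant
    input (1 - NDF/100); FYM/digestate uses the fixed 49/49/2 partition.
    """

    plant_c: tuple[float, ...]      # 12 monthly plant inputs
    dpm_fraction: tuple[float, ...]  # 12 monthly DPM shares
    fym_c: tuple[float, ...]        # 12 monthly organic-amendment inputs

    def __post_init__(self) -> None:
        for name, seq in (("plant_c", self.plant_c),
                          ("dpm_fraction", self.dpm_fraction),
                          ("fym_c", self.fym_c)):
            if len(seq) != 12:
                raise ValueError(f"{name} must have 12 monthly entries")
        if any(v < 0 for v in self.plant_c) or any(v < 0 for v in self.fym_c):
            raise ValueError("carbon inputs must be non-negative")
        if any(not 0.0 <= f <= 1.0 for f in self.dpm_fraction):
            raise ValueError("DPM fractions must lie in [0, 1]")

    @property
    def annual_plant_c(self) -> float:
        return float(sum(self.plant_c))

    def scaled(self, factor: float) -> "PlantInputSchedule":
        """Scale the plant inputs (not FYM) — the +/-20% sensitivity lever."""
        return replace(self, plant_c=tuple(v * factor for v in self.plant_c))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def falloon_iom(total_soc: float) -> float:
    """Inert organic matter from total SOC: 0.049 * SOC^1.139."""
    return 0.049 * total_soc ** 1.139


def init_pools(total_soc: float, clay: float) -> CarbonPools:
    """Pedotransfer initialisation of all five pools from measured SOC.

    RPM, HUM and BIO follow published regression functions of SOC and
    clay, IOM the Falloon power law, and DPM takes the residual so the
    pools sum exactly to the measured stock.
    """
    if total_soc <= 0:
        raise ValueError("total SOC must be positive")
    if not 0.0 < clay < 100.0:
        raise ValueError("clay must lie in (0, 100) %")
    iom = falloon_iom(total_soc)
    rpm = (0.1847 * total_soc + 0.1555) * (clay + 1.2750) ** -0.1158
    hum = (0.7148 * total_soc + 0.5069) * (clay + 0.3421) ** 0.0184
    bio = (0.0140 * total_soc + 0.0075) * (clay + 8.8473) ** -0.0567
    dpm = total_soc - (iom + rpm + hum + bio)
    if dpm < 0:
        raise ValueError(
            f"pedotransfer residual DPM is negative ({dpm:.3f} Mg C/ha) for "
            f"SOC={total_soc}, clay={clay}; pools not representable")
    return CarbonPools(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=iom)


# ---------------------------------------------------------------------------
# rate modifiers
# ---------------------------------------------------------------------------

def rate_modifiers(weather: WeatherMonth, smd: float, params: RothCParams) -> tuple[float, float, float]:
    """(a, b, c) for one month given the accumulated moisture deficit (mm).

    a = 47.91 / (1 + exp(106.06/(T + 18.27))); b declines linearly from 1
    to 0.2 once the deficit passes 44.4% of its maximum; c is 0.6 for
    covered soil, 1.0 for bare.
    """
    t = weather.temp_c
    a = 0.0 if t <= -18.27 else 47.91 / (1.0 + math.exp(106.06 / (t + 18.27)))
    max_smd = params.max_smd
    thresh = 0.444 * max_smd
    if smd <= thresh:
        b = 1.0
    else:
        b = 0.2 + 0.8 * (max_smd - smd) / (max_smd - thresh)
    c = 0.6 if params.covered else 1.0
    return a, b, c


def _update_smd(smd: float, weather: WeatherMonth, params: RothCParams) -> float:
    """Topsoil moisture deficit bookkeeping: deficit grows when 75% of
    open-pan evaporation exceeds rainfall, shrinks otherwise, within
    [0, max_smd]."""
    delta = 0.75 * weather.evap_mm - weather.rain_mm
    return float(np.clip(smd + delta, 0.0, params.max_smd))


def monthly_modifiers(weather: Sequence[WeatherMonth], params: RothCParams,
                      smd0: float = 0.0) -> list[tuple[float, float, float]]:
    """Rate modifiers along a weather series, carrying the deficit state."""
    out = []
    smd = smd0
    for w in weather:
        smd = _update_smd(smd, w, params)
        out.append(rate_modifiers(w, smd, params))
    return out


def periodic_year_modifiers(year: Sequence[WeatherMonth],
                            params: RothCParams) -> list[tuple[float, float, float]]:
    """Periodic (a,b,c) cycle of a repeated climate year.

    The deficit recursion converges to its cycle within a couple of
    repeats; the last repeat is returned.
    """
    if len(year) != 12:
        raise ValueError("baseline climate year must have 12 months")
    mods = monthly_modifiers(list(year) * 3, params)
    return mods[-12:]


# ---------------------------------------------------------------------------
# monthly step
# ---------------------------------------------------------------------------

def step_month(pools: CarbonPools, plant_c: float, dpm_fraction: float,
               fym_c: float, modifiers: tuple[float, float, float],
               params: RothCParams) -> tuple[CarbonPools, float]:
    """Advance one month; returns (new pools, CO2 evolved in Mg C/ha).

    Mass balance is exact: plant_c + fym_c = d(total SOC) + CO2.
    """
    a, b, c = modifiers
    abc = a * b * c
    x = np.asarray(pools.active(), dtype=float)
    k = np.asarray(params.k)
    decayed = x * (1.0 - np.exp(-k * abc / 12.0))
    d_total = float(decayed.sum())
    ratio = params.co2_ratio
    co2 = d_total * ratio / (ratio + 1.0)
    retained = d_total / (ratio + 1.0)
    to_bio = retained * params.bio_fraction
    to_hum = retained * (1.0 - params.bio_fraction)
    fd, fr, fh = params.fym_partition
    new = x - decayed
    new[0] += plant_c * dpm_fraction + fym_c * fd
    new[1] += plant_c * (1.0 - dpm_fraction) + fym_c * fr
    new[2] += to_bio
    new[3] += to_hum + fym_c * fh
    out = CarbonPools(dpm=float(new[0]), rpm=float(new[1]),
                      bio=float(new[2]), hum=float(new[3]), iom=pools.iom)
    return out, co2


def _step_active(x: np.ndarray, plant_c: float, dpm_fraction: float,
                 fym_c: float, abc: float, params: RothCParams,
                 k: np.ndarray) -> np.ndarray:
    """Active-pool step on a bare ndarray (hot loop / affine-map helper)."""
    decayed = x * (1.0 - np.exp(-k * abc / 12.0))
    ratio = params.co2_ratio
    retained = float(decayed.sum()) / (ratio + 1.0)
    fd, fr, fh = params.fym_partition
    new = x - decayed
    new[0] += plant_c * dpm_fraction + fym_c * fd
    new[1] += plant_c * (1.0 - dpm_fraction) + fym_c * fr
    new[2] += retained * params.bio_fraction
    new[3] += retained * (1.0 - params.bio_fraction) + fym_c * fh
    return new


# ---------------------------------------------------------------------------
# equilibrium inversion
# ---------------------------------------------------------------------------

def _annual_affine_map(schedule: PlantInputSchedule,
                       mods: Sequence[tuple[float, float, float]],
                       params: RothCParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A, b_plant, b_fym): active pools after one year are
    A @ x + I_annual * b_plant + b_fym, with I_annual scaling the plant
    schedule's monthly profile (normalised to unit annual sum)."""
    k = np.asarray(params.k)
    abcs = [a * b * c for a, b, c in mods]
    total_plant = schedule.annual_plant_c
    profile = [p / total_plant if total_plant > 0 else 1.0 / 12.0
               for p in schedule.plant_c]

    def run_year(x0: np.ndarray, plant_scale: float, fym_on: bool) -> np.ndarray:
        x = x0.copy()
        for m in range(12):
            x = _step_active(
                x, plant_scale * profile[m], schedule.dpm_fraction[m],
                schedule.fym_c[m] if fym_on else 0.0, abcs[m], params, k)
        return x

    zero = np.zeros(4)
    a_cols = [run_year(e, 0.0, False) for e in np.eye(4)]
    A = np.column_stack(a_cols)
    b_plant = run_year(zero, 1.0, False)
    b_fym = run_year(zero, 0.0, True)
    return A, b_plant, b_fym


def spin_to_equilibrium(target_soc: float, clay: float,
                        baseline_year: Sequence[WeatherMonth],
                        schedule: PlantInputSchedule,
                        params: RothCParams | None = None,
                        tol: float = 1e-6) -> float:
    """Annual plant C input (Mg C/ha/yr) holding SOC at ``target_soc``.

    Under a repeated climate year the active pools follow an affine annual
    map, so the steady state is linear in the annual plant input and the
    inversion is a single solve; the result is verified against the
    steady-state residual at ``tol`` (Mg C/ha).
    """
    params = replace(params or RothCParams(), clay=clay)
    iom = falloon_iom(target_soc)
    active_target = target_soc - iom
    if active_target <= 0:
        raise ValueError(
            f"target SOC {target_soc} is not above its inert pool {iom:.3f}")
    mods = periodic_year_modifiers(baseline_year, params)
    A, b_plant, b_fym = _annual_affine_map(schedule, mods, params)
    m = np.eye(4) - A
    s_plant = float(np.linalg.solve(m, b_plant).sum())
    s_fym = float(np.linalg.solve(m, b_fym).sum())
    annual_input = (active_target - s_fym) / s_plant
    if annual_input <= 0:
        raise ValueError(
            f"equilibrium inversion infeasible: organic amendments alone "
            f"({s_fym:.2f} Mg C/ha at steady state) exceed the target's "
            f"active stock ({active_target:.2f})")
    # verification: fixed-point residual of the affine map
    x_star = np.linalg.solve(m, annual_input * b_plant + b_fym)
    resid = abs(float(x_star.sum()) - active_target)
    if resid > max(tol, 1e-9 * active_target):
        raise RuntimeError(f"equilibrium residual {resid:.3e} exceeds tolerance")
    return annual_input


def steady_state_pools(annual_plant_c: float, iom: float,
                       baseline_year: Sequence[WeatherMonth],
                       schedule: PlantInputSchedule,
                       params: RothCParams | None = None) -> CarbonPools:
    """Steady-state pool distribution under a repeated climate year."""
    params = params or RothCParams()
    mods = periodic_year_modifiers(baseline_year, params)
    A, b_plant, b_fym = _annual_affine_map(schedule, mods, params)
    x = np.linalg.solve(np.eye(4) - A, annual_plant_c * b_plant + b_fym)
    return CarbonPools(dpm=float(x[0]), rpm=float(x[1]), bio=float(x[2]),
                       hum=float(x[3]), iom=iom)


# ---------------------------------------------------------------------------
# plant input partitioning
# ---------------------------------------------------------------------------

#: Monthly share of annual plant C input (temperate grassland growth curve).
GROWTH_PROFILE: tuple[float, ...] = (
    0.01, 0.02, 0.05, 0.10, 0.145, 0.15, 0.135, 0.12, 0.11, 0.09, 0.04, 0.02)

#: Fraction of aboveground biomass harvested or consumed by stock.
HARVESTED_FRACTION = 0.65
#: Annual turnover of the unharvested aboveground fraction.
ABOVEGROUND_TURNOVER = 0.5
#: Net rhizodeposition : belowground biomass ratio for grassland species.
RHIZODEPOSITION_RATIO = 0.5
#: Carbon concentration of plant biomass.
PLANT_C_CONCENTRATION = 0.45


@dataclass(frozen=True)
class PlantInputPartition:
    """Component breakdown of the annual soil C input (Mg C/ha/yr)."""

    aboveground_residue_c: float
    belowground_c: float
    rhizodeposition_c: float
    total_c: float


def partition_plant_inputs(aboveground_biomass_dm: float,
                           equilibrium_total_input: float,
                           ndf_by_month: Sequence[float],
                           fym_c_by_month: Sequence[float] | None = None,
                           monthly_profile: Sequence[float] = GROWTH_PROFILE,
                           ) -> tuple[PlantInputSchedule, PlantInputPartition]:
    """Partition the equilibrium C input into residue components and a
    monthly schedule.

    Aboveground residue C is 17.5% of aboveground biomass C (65% of the
    biomass is harvested or grazed; half the remaining 35% turns over
    annually).  Belowground input is the remainder of the equilibrium
    total, of which net rhizodeposition is half the belowground biomass.
    The DPM fraction of each month's input is 1 - NDF/100.
    """
    if aboveground_biomass_dm <= 0:
        raise ValueError("aboveground biomass must be positive")
    if any(not 0.0 < v < 100.0 for v in ndf_by_month):
        raise ValueError("NDF values must lie in (0, 100)")
    if len(ndf_by_month) != 12:
        raise ValueError("ndf_by_month must have 12 entries")
    agb_c = PLANT_C_CONCENTRATION * aboveground_biomass_dm / 1000.0  # Mg C/ha
    above_res = (1.0 - HARVESTED_FRACTION) * ABOVEGROUND_TURNOVER * agb_c
    below = equilibrium_total_input - above_res
    if below < 0:
        raise ValueError(
            f"equilibrium input {equilibrium_total_input:.2f} Mg C/ha is "
            f"smaller than the aboveground residue alone ({above_res:.2f}); "
            "check biomass and equilibrium inputs")
    # rhizodeposition = 0.5 x belowground biomass C; with root turnover also
    # ~0.5/yr the belowground biomass equals the total belowground input
    rhizo = RHIZODEPOSITION_RATIO * below
    profile = np.asarray(monthly_profile, dtype=float)
    profile = profile / profile.sum()
    plant_c = tuple(float(equilibrium_total_input * p) for p in profile)
    dpm_fraction = tuple(1.0 - v / 100.0 for v in ndf_by_month)
    fym = tuple(fym_c_by_month) if fym_c_by_month is not None else (0.0,) * 12
    schedule = PlantInputSchedule(plant_c=plant_c, dpm_fraction=dpm_fraction,
                                  fym_c=fym)
    part = PlantInputPartition(
        aboveground_residue_c=above_res, belowground_c=below,
        rhizodeposition_c=rhizo, total_c=equilibrium_total_input)
    return schedule, part


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

@dataclass
class SOCProjection:
    """Result of a multi-decade SOC run."""

    trajectory: pd.DataFrame     # year-end pools, total, cumulative CO2
    initial_soc: float
    final_soc: float
    annual_change_rate: float    # Mg C/ha/yr over the averaging window
    window_years: float


def run_projection(initial_pools: CarbonPools, schedule: PlantInputSchedule,
                   weather: Sequence[WeatherMonth],
                   params: RothCParams | None = None,
                   rate_window_years: float = 100.0) -> SOCProjection:
    """Run the monthly model over a weather series (whole years).

    The annual SOC change rate is (final - initial) / ``rate_window_years``
    — the averaging window is a reporting convention, fixed at the 100-yr
    impact horizon by default, and does not affect the simulation.
    """
    params = params or RothCParams()
    if len(weather) % 12 != 0:
        raise ValueError("weather series must cover whole years")
    mods = monthly_modifiers(weather, params)
    pools = initial_pools
    co2_cum = 0.0
    rows = []
    for i, (w, mod) in enumerate(zip(weather, mods)):
        m = i % 12
        pools, co2 = step_month(pools, schedule.plant_c[m],
                                schedule.dpm_fraction[m], schedule.fym_c[m],
                                mod, params)
        co2_cum += co2
        if m == 11:
            rows.append({"year": w.year, "dpm": pools.dpm, "rpm": pools.rpm,
                         "bio": pools.bio, "hum": pools.hum, "iom": pools.iom,
                         "total": pools.total, "co2_cum": co2_cum})
    df = pd.DataFrame(rows)
    final = pools.total
    rate = (final - initial_pools.total) / rate_window_years
    return SOCProjection(trajectory=df, initial_soc=initial_pools.total,
                         final_soc=final, annual_change_rate=rate,
                         window_years=rate_window_years)
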