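"""Seed-reproducible synthetic farm data.

Generators for the four primary-data streams the analysis consumes — herd
weighing records, monthly weather, monthly forage quality, and the farm
input inventory — with the statistical structure of a lowland beef
finishing enterprise on permanent pasture in south-west England
(North Wyke Farm Platform style): ~30 weaned calves entering each autumn
at ~332 kg, housed October–April on silage, grazed otherwise, finished at
~555 kg (heifers) / ~620 kg (steers), with liveweight recorded every 2–4
weeks.

All generators take an integer ``seed`` and are byte-reproducible: the same
arguments with the same seed return identical objects.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnimalRecord",
    "FarmInventory",
    "ForageMonth",
    "WeatherMonth",
    "DEVON_NORMALS",
    "default_inventory",
    "generate_forage_series",
    "generate_herd",
    "generate_weather",
    "herd_to_frame",
    "weather_to_frame",
    "forage_to_frame",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FarmInventory:
    """Annual material inputs of the finishing enterprise.

    Masses in kg/yr, areas in ha, yield in kg DM/ha/yr, transport in
    t*km/yr, clay as % of topsoil mass, initial_soc in Mg C/ha.
    """

    farm_area: float = 21.61
    fertilised_area: float = 21.24
    yield_dm: float = 11_867.0
    fert_n: float = 3354.0
    fert_p: float = 257.0
    fert_k: float = 1198.0
    lime: float = 3831.0
    rapeseed_meal: float = 1927.0
    straw: float = 38_728.0
    transport_tkm: dict[str, float] = field(
        default_factory=lambda: {
            "rapeseed_road": 44.0,
            "straw_road": 2424.0,
            "fertiliser_road": 3698.0,
        }
    )
    seed_kg: float = 0.0
    dcd_kg: float = 0.0
    clay_content: float = 36.0
    initial_soc: float = 53.78

    def __post_init__(self) -> None:
        scalars = (
            self.farm_area, self.fertilised_area, self.yield_dm, self.fert_n,
            self.fert_p, self.fert_k, self.lime, self.rapeseed_meal,
            self.straw, self.seed_kg, self.dcd_kg,
        )
        if any(v < 0 for v in scalars) or any(v < 0 for v in self.transport_tkm.values()):
            raise ValueError("inventory masses/areas must be non-negative")
        if self.fertilised_area > self.farm_area:
            raise ValueError("fertilised_area cannot exceed farm_area")


@dataclass(frozen=True)
class AnimalRecord:
    """One finishing animal and its weighing history."""

    id: str
    sex: str  # "steer" | "heifer"
    entry_date: dt.date
    weighings: tuple[tuple[dt.date, float], ...]
    exit_date: dt.date

    def __post_init__(self) -> None:
        if self.sex not in ("steer", "heifer"):
            raise ValueError(f"unknown sex {self.sex!r}")
        dates = [d for d, _ in self.weighings]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("weighing dates must be strictly increasing")
        if any(w <= 0 for _, w in self.weighings):
            raise ValueError("liveweights must be positive")
        if self.weighings and self.weighings[-1][1] < self.weighings[0][1]:
            raise ValueError("exit weight below entry weight")

    @property
    def entry_weight(self) -> float:
        return self.weighings[0][1]

    @property
    def exit_weight(self) -> float:
        return self.weighings[-1][1]

    @property
    def liveweight_gain(self) -> float:
        return self.exit_weight - self.entry_weight

    @property
    def residency_days(self) -> int:
        return (self.weighings[-1][0] - self.weighings[0][0]).days


@dataclass(frozen=True)
class ForageMonth:
    """Diet quality of one forage source in one calendar month.

    DE is digestible energy as % of gross energy, CP crude protein as
    % of DM, NDF neutral detergent fibre as % of DM (the litter-quality
    proxy feeding the soil model's DPM:RPM split).
    """

    month: int
    source: str  # "pasture" | "silage"
    de_pct: float
    cp_pct: float
    ndf_pct: float

    def __post_init__(self) -> None:
        for name, v in (("DE", self.de_pct), ("CP", self.cp_pct), ("NDF", self.ndf_pct)):
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if self.source not in ("pasture", "silage"):
            raise ValueError(f"unknown forage source {self.source!r}")


@dataclass(frozen=True)
class WeatherMonth:
    """Monthly climate driver for the soil model."""

    year: int
    month: int
    temp_c: float
    rain_mm: float
    evap_mm: float

    def __post_init__(self) -> None:
        if self.rain_mm < 0 or self.evap_mm < 0:
            raise ValueError("rainfall and evaporation must be non-negative")
        if not math.isfinite(self.temp_c):
            raise ValueError("temperature must be finite")


# ---------------------------------------------------------------------------
# packaged climate normals (illustrative Devon lowland values)
# ---------------------------------------------------------------------------

#: Monthly normals (Jan..Dec): mean air temperature degC, rainfall mm,
#: open-pan evaporation mm.  Illustrative values for a mild, wet lowland
#: site in Devon; the real analysis would use station records.
DEVON_NORMALS: dict[str, tuple[float, ...]] = {
    "temp_c": (4.6, 4.8, 6.3, 8.3, 11.2, 13.9, 15.9, 15.7, 13.7, 10.7, 7.3, 5.2),
    "rain_mm": (108.0, 86.0, 78.0, 68.0, 62.0, 58.0, 60.0, 70.0, 72.0, 100.0, 110.0, 116.0),
    "evap_mm": (8.0, 15.0, 32.0, 55.0, 76.0, 86.0, 90.0, 75.0, 50.0, 28.0, 12.0, 7.0),
}

#: Default finishing targets by sex, kg liveweight.
EXIT_TARGETS: dict[str, float] = {"heifer": 555.0, "steer": 620.0}

#: Baseline forage quality: DE % of GE, CP % of DM, NDF % of DM.
PASTURE_QUALITY: tuple[float, float, float] = (74.86, 23.10, 46.0)
SILAGE_QUALITY: tuple[float, float, float] = (69.40, 15.46, 52.0)

#: Housing window: animals are in the barn 1 October - 30 April.
HOUSED_MONTHS: frozenset[int] = frozenset({10, 11, 12, 1, 2, 3, 4})


def month_is_housed(month: int) -> bool:
    return month in HOUSED_MONTHS


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def default_inventory() -> FarmInventory:
    """Baseline inventory of the permanent-pasture finishing system."""
    return FarmInventory()


def generate_herd(
    n_animals: int = 30,
    entry_mean_kg: float = 332.0,
    entry_sd_kg: float = 10.0,
    exit_targets: dict[str, float] | None = None,
    entry_date: dt.date = dt.date(2015, 10, 5),
    entry_jitter_days: int = 5,
    weighing_interval: tuple[int, int] = (14, 28),
    adg_mean: float = 0.90,
    adg_cv: float = 0.12,
    period_adg_sigma: float = 0.30,
    seed: int = 0,
) -> list[AnimalRecord]:
    """Generate a finishing herd with per-animal weighing histories.

    Each animal follows a piecewise-linear liveweight trajectory from a
    draw around ``entry_mean_kg`` to its sex-specific finishing target,
    with weighings every ``weighing_interval`` days and per-period
    lognormal multipliers on the average daily gain (ADG), rescaled so the
    final weighing hits the target exactly.  Sexes alternate so the herd
    splits evenly between steers and heifers.

    Parameters
    ----------
    adg_mean, adg_cv
        Mean and coefficient of variation of the per-animal overall ADG
        (kg/d); per-period multipliers add within-animal variation with
        lognormal sigma ``period_adg_sigma``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if entry_mean_kg <= 0:
        raise ValueError("entry_mean_kg must be positive")
    lo, hi = weighing_interval
    if not (14 <= lo <= hi <= 28):
        raise ValueError("weighing interval must lie within [14, 28] days")
    targets = dict(EXIT_TARGETS if exit_targets is None else exit_targets)
    if any(v <= 0 for v in targets.values()):
        raise ValueError("exit targets must be positive")

    rng = np.random.default_rng(seed)
    herd: list[AnimalRecord] = []
    for i in range(n_animals):
        sex = "steer" if i % 2 == 0 else "heifer"
        target = targets[sex]
        entry_w = float(np.clip(rng.normal(entry_mean_kg, entry_sd_kg),
                                0.5 * entry_mean_kg, 1.5 * entry_mean_kg))
        entry_w = min(entry_w, target - 1.0)
        adg = adg_mean * float(rng.lognormal(-0.5 * (adg_cv ** 2), adg_cv))
        start = entry_date + dt.timedelta(days=int(rng.integers(-entry_jitter_days,
                                                                entry_jitter_days + 1)))
        total_days = max(int(round((target - entry_w) / adg)), lo)

        # weighing grid: successive uniform draws in [lo, hi] days
        offsets = [0]
        while offsets[-1] < total_days:
            offsets.append(offsets[-1] + int(rng.integers(lo, hi + 1)))
        offsets[-1] = max(offsets[-1], total_days)

        # per-period lognormal ADG multipliers, rescaled to hit the target
        n_per = len(offsets) - 1
        mult = rng.lognormal(-0.5 * period_adg_sigma ** 2, period_adg_sigma, n_per)
        days_per = np.diff(offsets)
        gains = mult * days_per
        gains *= (target - entry_w) / gains.sum()
        weights = entry_w + np.concatenate(([0.0], np.cumsum(gains)))

        weighings = tuple(
            (start + dt.timedelta(days=int(o)), float(round(w, 1)))
            for o, w in zip(offsets, weights)
        )
        herd.append(AnimalRecord(
            id=f"A{i + 1:03d}", sex=sex, entry_date=start,
            weighings=weighings, exit_date=weighings[-1][0],
        ))
    return herd


def generate_weather(
    start_year: int = 2016,
    n_years: int = 85,
    trajectory: str = "rcp26_like",
    normals: dict[str, tuple[float, ...]] | None = None,
    warming_by_2100: dict[str, float] | None = None,
    noise_sd_temp: float = 0.6,
    noise_cv_rain: float = 0.15,
    seed: int = 0,
) -> list[WeatherMonth]:
    """Generate a monthly climate series under a stylised warming pathway.

    The series is the seasonal normal cycle plus a linear warming ramp
    reaching the trajectory's end-of-century increment (defaults:
    +1.5 degC for ``rcp26_like``, +4.0 degC for ``rcp85_like``, 0 for
    ``flat``) plus optional Gaussian noise.  Rainfall and evaporation keep
    their seasonal normals (multiplicative noise on rain only), so the two
    pathways differ strictly through temperature — the ordering the soil
    projections rely on.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    ramps = {"rcp26_like": 1.5, "rcp85_like": 4.0, "flat": 0.0}
    if warming_by_2100:
        ramps.update(warming_by_2100)
    if trajectory not in ramps:
        raise ValueError(f"unknown trajectory {trajectory!r}; expected one of {sorted(ramps)}")
    nrm = DEVON_NORMALS if normals is None else normals
    ramp_end = ramps[trajectory]
    span = max((start_year + n_years - 1) - start_year, 1)

    rng = np.random.default_rng(seed)
    out: list[WeatherMonth] = []
    for y in range(start_year, start_year + n_years):
        warm = ramp_end * (y - start_year) / span
        for m in range(1, 13):
            t = nrm["temp_c"][m - 1] + warm
            r = nrm["rain_mm"][m - 1]
            e = nrm["evap_mm"][m - 1]
            if noise_sd_temp > 0:
                t += float(rng.normal(0.0, noise_sd_temp))
            if noise_cv_rain > 0:
                r *= float(np.clip(rng.normal(1.0, noise_cv_rain), 0.0, None))
            out.append(WeatherMonth(year=y, month=m, temp_c=round(t, 3),
                                    rain_mm=round(r, 2), evap_mm=round(e, 2)))
    return out


def generate_forage_series(
    n_months: int = 12,
    pasture_quality: tuple[float, float, float] = PASTURE_QUALITY,
    silage_quality: tuple[float, float, float] = SILAGE_QUALITY,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ForageMonth]:
    """Monthly DE/CP/NDF series for both forage sources.

    With ``noise_sd == 0`` every month carries the target values exactly;
    otherwise independent Gaussian noise (sd in percentage points) is
    added, truncated to (0, 100).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for q in (*pasture_quality, *silage_quality):
        if not 0.0 < q < 100.0:
            raise ValueError("quality targets must lie in (0, 100)")
    rng = np.random.default_rng(seed)

    def _noisy(v: float) -> float:
        if noise_sd == 0:
            return v
        return float(np.clip(v + rng.normal(0.0, noise_sd), 1e-3, 100 - 1e-3))

    out: list[ForageMonth] = []
    for i in range(n_months):
        m = i % 12 + 1
        de, cp, ndf = pasture_quality
        out.append(ForageMonth(m, "pasture", _noisy(de), _noisy(cp), _noisy(ndf)))
        de, cp, ndf = silage_quality
        out.append(ForageMonth(m, "silage", _noisy(de), _noisy(cp), _noisy(ndf)))
    return out


# ---------------------------------------------------------------------------
# CSV writers (ISO-8601 dates, header row mandatory)
# ---------------------------------------------------------------------------

def herd_to_frame(herd: Iterable[AnimalRecord]) -> pd.DataFrame:
    rows = [
        {"animal_id": a.id, "date": d.isoformat(), "liveweight_kg": w}
        for a in herd for d, w in a.weighings
    ]
    return pd.DataFrame(rows, columns=["animal_id", "date", "liveweight_kg"])


def weather_to_frame(series: Iterable[WeatherMonth]) -> pd.DataFrame:
    rows = [
        {"year": w.year, "month": w.month, "temp_c": w.temp_c,
         "rain_mm": w.rain_mm, "evap_mm": w.evap_mm}
        for w in series
    ]
    return pd.DataFrame(rows, columns=["year", "month", "temp_c", "rain_mm", "evap_mm"])


def forage_to_frame(series: Iterable[ForageMonth]) -> pd.DataFrame:
    rows = [
        {"month": f.month, "source": f.source, "de_pct": f.de_pct,
         "cp_pct": f.cp_pct, "ndf_pct": f.ndf_pct}
        for f in series
    ]
    return pd.DataFrame(rows, columns=["month", "source", "de_pct", "cp_pct", "ndf_pct"])


def weather_from_frame(df: pd.DataFrame) -> list[WeatherMonth]:
    return [
        WeatherMonth(int(r.year), int(r.month), float(r.temp_c),
                     float(r.rain_mm), float(r.evap_mm))
        for r in df.itertuples()
    ]
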