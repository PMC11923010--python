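"""RothC: initialisation, modifiers, mass balance, equilibrium inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grazefoot.rothc_soil import (
    CarbonPools, PlantInputSchedule, RothCParams, falloon_iom, init_pools,
    monthly_modifiers, partition_plant_inputs, periodic_year_modifiers,
    rate_modifiers, run_projection, spin_to_equilibrium, steady_state_pools,
    step_month,
)
from grazefoot.synthetic_farm import WeatherMonth, generate_weather


BASE_YEAR = generate_weather(2015, 1, "flat", noise_sd_temp=0.0,
                             noise_cv_rain=0.0, seed=0)


def flat_schedule(annual_plant=3.0, dpm_frac=0.54, fym=0.0):
    return PlantInputSchedule(plant_c=(annual_plant / 12.0,) * 12,
                              dpm_fraction=(dpm_frac,) * 12,
                              fym_c=(fym / 12.0,) * 12)


class TestInitPools:
    def test_inert_pool_follows_power_law(self):
        pools = init_pools(53.78, 36.0)
        assert pools.iom == pytest.approx(0.049 * 53.78 ** 1.139, rel=1e-12)
        assert pools.iom == pytest.approx(4.59, abs=0.01)

    def test_pedotransfer_pools_match_direct_formula_evaluation(self):
        soc, clay = 53.78, 36.0
        pools = init_pools(soc, clay)
        assert pools.rpm == pytest.approx(
            (0.1847 * soc + 0.1555) * (clay + 1.2750) ** -0.1158, rel=1e-12)
        assert pools.hum == pytest.approx(
            (0.7148 * soc + 0.5069) * (clay + 0.3421) ** 0.0184, rel=1e-12)
        assert pools.bio == pytest.approx(
            (0.0140 * soc + 0.0075) * (clay + 8.8473) ** -0.0567, rel=1e-12)

    @given(st.floats(min_value=30.0, max_value=120.0))
    def test_pools_sum_to_measured_stock(self, soc):
        assert init_pools(soc, 36.0).total == pytest.approx(soc, rel=1e-12)

    def test_low_stock_yields_negative_residual_diagnostic(self):
        with pytest.raises(ValueError, match="residual DPM"):
            init_pools(1.0, 36.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            init_pools(-1.0, 36.0)
        with pytest.raises(ValueError):
            init_pools(50.0, 0.0)


class TestRateModifiers:
    def test_temperature_modifier_near_unity_at_9_25_degrees(self):
        w = WeatherMonth(2016, 1, 9.25, 50.0, 10.0)
        a, _, _ = rate_modifiers(w, 0.0, RothCParams())
        assert a == pytest.approx(47.91 / (1 + math.exp(106.06 / (9.25 + 18.27))),
                                  rel=1e-12)
        assert a == pytest.approx(1.0, abs=0.01)

    def test_saturated_month_has_full_moisture_modifier(self):
        w = WeatherMonth(2016, 1, 10.0, 120.0, 10.0)
        _, b, _ = rate_modifiers(w, 0.0, RothCParams())
        assert b == 1.0

    def test_cover_modifier(self):
        w = WeatherMonth(2016, 7, 15.0, 60.0, 90.0)
        assert rate_modifiers(w, 0.0, RothCParams(covered=True))[2] == 0.6
        assert rate_modifiers(w, 0.0, RothCParams(covered=False))[2] == 1.0

    def test_moisture_modifier_bounded_on_dry_series(self):
        params = RothCParams()
        dry = [WeatherMonth(2016, m, 15.0, 0.0, 120.0) for m in range(1, 13)]
        for _, b, _ in monthly_modifiers(dry, params):
            assert 0.2 - 1e-12 <= b <= 1.0


class TestStepMonth:
    def test_empty_soil_stays_empty(self):
        pools = CarbonPools(0, 0, 0, 0, 0)
        out, co2 = step_month(pools, 0.0, 0.5, 0.0, (1.0, 1.0, 1.0), RothCParams())
        assert out.total == 0.0 and co2 == 0.0

    def test_single_pool_decay_matches_closed_form(self):
        params = RothCParams(covered=False)
        pools = CarbonPools(1.0, 0, 0, 0, 0)
        out, co2 = step_month(pools, 0.0, 0.5, 0.0, (1.0, 1.0, 1.0), params)
        decayed = 1.0 - math.exp(-10.0 / 12.0)
        assert out.dpm == pytest.approx(math.exp(-10.0 / 12.0), rel=1e-12)
        x = params.co2_ratio
        assert co2 == pytest.approx(decayed * x / (x + 1), rel=1e-12)

    def test_no_decay_limit_adds_input_exactly(self):
        pools = CarbonPools(1.0, 2.0, 0.5, 10.0, 3.0)
        out, co2 = step_month(pools, 1.0, 0.5, 0.0, (0.0, 1.0, 1.0), RothCParams())
        assert co2 == 0.0
        assert out.total == pytest.approx(pools.total + 1.0, rel=1e-12)

    @given(st.floats(0.0, 10.0), st.floats(0.0, 30.0), st.floats(0.0, 5.0),
           st.floats(0.0, 60.0), st.floats(0.0, 2.0), st.floats(0.0, 1.0),
           st.floats(0.0, 0.5))
    def test_mass_balance_exact(self, dpm, rpm, bio, hum, plant, dpm_frac, fym):
        pools = CarbonPools(dpm, rpm, bio, hum, 4.0)
        out, co2 = step_month(pools, plant, dpm_frac, fym, (0.9, 0.7, 0.6),
                              RothCParams())
        lhs = plant + fym
        rhs = (out.total - pools.total) + co2
        assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, pools.total))

    def test_inert_pool_never_changes(self):
        pools = CarbonPools(1, 2, 3, 4, 7.77)
        out, _ = step_month(pools, 1.0, 0.5, 0.5, (1.0, 0.8, 0.6), RothCParams())
        assert out.iom == 7.77


class TestEquilibrium:
    def test_inversion_recovers_known_input(self):
        params = RothCParams(clay=36.0)
        schedule = flat_schedule(annual_plant=1.0, fym=0.8)
        target_active = steady_state_pools(3.0, 0.0, BASE_YEAR, schedule,
                                           params).total
        # choose the target SOC whose active part equals the steady state
        lo, hi = target_active, target_active + 30.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mid - falloon_iom(mid) < target_active:
                lo = mid
            else:
                hi = mid
        target = 0.5 * (lo + hi)
        rec = spin_to_equilibrium(target, 36.0, BASE_YEAR, schedule, params)
        assert rec == pytest.approx(3.0, rel=1e-6)

    def test_steady_state_is_a_fixed_point_over_centuries(self):
        params = RothCParams(clay=36.0)
        schedule = flat_schedule(fym=0.5)
        target = 53.78
        inp = spin_to_equilibrium(target, 36.0, BASE_YEAR, schedule, params)
        pools = steady_state_pools(inp, falloon_iom(target), BASE_YEAR,
                                   PlantInputSchedule(
                                       plant_c=tuple(inp / 12.0 for _ in range(12)),
                                       dpm_fraction=schedule.dpm_fraction,
                                       fym_c=schedule.fym_c), params)
        assert pools.total == pytest.approx(target, rel=1e-9)
        run = PlantInputSchedule(plant_c=tuple(inp / 12.0 for _ in range(12)),
                                 dpm_fraction=schedule.dpm_fraction,
                                 fym_c=schedule.fym_c)
        mods = periodic_year_modifiers(BASE_YEAR, params)
        for _ in range(500):
            for m in range(12):
                pools, _ = step_month(pools, run.plant_c[m], run.dpm_fraction[m],
                                      run.fym_c[m], mods[m], params)
        assert abs(pools.total - target) / target < 1e-3

    def test_higher_target_needs_more_input(self):
        params = RothCParams(clay=36.0)
        schedule = flat_schedule(fym=0.5)
        i1 = spin_to_equilibrium(40.0, 36.0, BASE_YEAR, schedule, params)
        i2 = spin_to_equilibrium(80.0, 36.0, BASE_YEAR, schedule, params)
        assert i2 > i1 > 0

    def test_amendments_exceeding_target_are_infeasible(self):
        params = RothCParams(clay=36.0)
        schedule = flat_schedule(fym=50.0)
        with pytest.raises(ValueError, match="infeasible"):
            spin_to_equilibrium(20.0, 36.0, BASE_YEAR, schedule, params)


class TestPartition:
    NDF = (46.0,) * 12

    def test_aboveground_residue_is_17_5_pct_of_biomass_carbon(self):
        # 100 Mg C of aboveground biomass = 222.22 t DM/ha at 45% C
        agb_dm = 100.0 / 0.45 * 1000.0
        _, part = partition_plant_inputs(agb_dm, 30.0, self.NDF)
        assert part.aboveground_residue_c == pytest.approx(17.5, rel=1e-12)

    def test_carbon_concentration_of_biomass(self):
        _, part = partition_plant_inputs(1000.0, 5.0, self.NDF)
        # 1000 kg DM -> 450 kg C -> 0.45 Mg C; residue = 17.5% of that
        assert part.aboveground_residue_c == pytest.approx(0.175 * 0.45, rel=1e-12)

    def test_ndf_sets_litter_quality_split(self):
        sched, _ = partition_plant_inputs(11867.0, 4.0, (45.0,) * 12)
        assert all(f == pytest.approx(0.55, rel=1e-12) for f in sched.dpm_fraction)

    def test_equilibrium_input_below_aboveground_residue_errors(self):
        with pytest.raises(ValueError, match="aboveground residue"):
            partition_plant_inputs(100000.0 / 0.45 * 1000.0, 1.0, self.NDF)

    def test_rhizodeposition_is_half_belowground(self):
        _, part = partition_plant_inputs(11867.0, 4.0, self.NDF)
        assert part.rhizodeposition_c == pytest.approx(0.5 * part.belowground_c,
                                                       rel=1e-12)


class TestProjection:
    def test_input_scaling_brackets_final_stock(self):
        weather = generate_weather(2016, 30, "rcp26_like", noise_sd_temp=0.0,
                                   noise_cv_rain=0.0, seed=0)
        pools0 = init_pools(53.78, 36.0)
        runs = {}
        for scale in (0.8, 1.0, 1.2):
            sched = flat_schedule(annual_plant=3.0 * scale, fym=0.5)
            runs[scale] = run_projection(pools0, sched, weather).final_soc
        assert runs[0.8] < runs[1.0] < runs[1.2]

    def test_warmer_pathway_decomposes_more(self):
        kw = dict(noise_sd_temp=0.0, noise_cv_rain=0.0, seed=0)
        pools0 = init_pools(53.78, 36.0)
        sched = flat_schedule(annual_plant=3.0, fym=0.5)
        cool = run_projection(pools0, sched,
                              generate_weather(2016, 40, "rcp26_like", **kw))
        warm = run_projection(pools0, sched,
                              generate_weather(2016, 40, "rcp85_like", **kw))
        assert warm.final_soc < cool.final_soc

    def test_trajectory_bookkeeping_matches_mass_balance(self):
        weather = generate_weather(2016, 10, "flat", noise_sd_temp=0.0,
                                   noise_cv_rain=0.0, seed=0)
        pools0 = init_pools(53.78, 36.0)
        sched = flat_schedule(annual_plant=3.0, fym=0.5)
        proj = run_projection(pools0, sched, weather)
        inputs = 10 * (3.0 + 0.5)
        d_soc = proj.final_soc - proj.initial_soc
        co2 = proj.trajectory["co2_cum"].iloc[-1]
        assert inputs == pytest.approx(d_soc + co2, abs=1e-9 * inputs)
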