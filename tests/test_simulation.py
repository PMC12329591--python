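import dataclasses
import datetime as dt

import pandas as pd
import pytest

from plantainforage import (
    DefoliationRule,
    ManagementEvent,
    Organ,
    SimulationParams,
    defoliate,
    run_simulation,
    season_accumulate,
    season_label,
)
from plantainforage.arbitrator import new_pools
from plantainforage.simulation import ScheduleError, residual_fraction
from plantainforage.canopy import CanopyParams, height_from_leaf
from plantainforage.soil import default_profile

from conftest import LATITUDE, constant_weather, sow_event


def grown_pools():
    pools = new_pools()
    pools[Organ.LEAF].dm_structural = 150.0
    pools[Organ.LEAF].dm_dead = 20.0
    pools[Organ.LEAF].n_live = 150.0 * 0.035
    pools[Organ.LEAF].n_dead = 20.0 * 0.023
    pools[Organ.STEM].dm_structural = 30.0
    pools[Organ.STEM].n_live = 30.0 * 0.025
    pools[Organ.ROOT].dm_structural = 60.0
    pools[Organ.ROOT].n_live = 60.0 * 0.015
    return pools


class TestDefoliate:
    def test_zero_fractions_noop(self):
        pools = grown_pools()
        before = pools[Organ.LEAF].dm_live
        rec = defoliate(pools, {}, dt.date(2000, 11, 1))
        assert pools[Organ.LEAF].dm_live == before
        assert rec.total_dm_kg_ha == 0.0

    def test_full_leaf_removal_spares_other_organs(self):
        pools = grown_pools()
        defoliate(pools, {Organ.LEAF: 1.0}, dt.date(2000, 11, 1))
        assert pools[Organ.LEAF].dm_live == 0.0
        assert pools[Organ.LEAF].dm_dead == 0.0
        assert pools[Organ.STEM].dm_live == pytest.approx(30.0)
        assert pools[Organ.ROOT].dm_live == pytest.approx(60.0)

    def test_below_ground_never_touched(self):
        pools = grown_pools()
        defoliate(pools, {o: 0.8 for o in Organ}, dt.date(2000, 11, 1))
        assert pools[Organ.ROOT].dm_live == pytest.approx(60.0)

    def test_removed_amounts_in_kg_ha(self):
        pools = grown_pools()
        rec = defoliate(pools, {Organ.LEAF: 0.5}, dt.date(2000, 11, 1))
        # half of (150 live + 20 dead) g/m2 = 85 g/m2 = 850 kg/ha
        assert rec.removed_dm[Organ.LEAF] == pytest.approx(850.0)
        assert 0.0 < rec.n_concentration < 0.06

    def test_residual_height_inverse(self):
        params = CanopyParams()
        leaf_g_m2 = 150.0
        frac = residual_fraction(leaf_g_m2, residual_height_mm=70.0, params=params)
        remaining_kg_ha = leaf_g_m2 * 10 * (1 - frac)
        assert height_from_leaf(remaining_kg_ha, params) == pytest.approx(70.0, abs=0.5)


class TestSeasonAccounting:
    def test_window_boundaries(self):
        assert season_label(dt.date(2014, 8, 1)) == season_label(dt.date(2015, 3, 1))
        assert season_label(dt.date(2015, 6, 30)) != season_label(dt.date(2015, 7, 1))

    def test_totals_partition_all_records(self):
        df = pd.DataFrame({
            "date": [dt.date(2014, 8, 1), dt.date(2015, 3, 1), dt.date(2015, 7, 2)],
            "total_dm_kg_ha": [1000.0, 800.0, 1200.0],
            "removed_n_kg_ha": [30.0, 25.0, 40.0],
        })
        out = season_accumulate(df)
        assert out["dm_kg_ha"].sum() == pytest.approx(3000.0)
        assert out["n_kg_ha"].sum() == pytest.approx(95.0)
        assert len(out) == 2


class TestRunSimulation:
    def test_determinism(self, two_year_weather, default_params):
        events = [sow_event()]
        d1, h1, _ = run_simulation(two_year_weather, default_params, events=events)
        d2, h2, _ = run_simulation(two_year_weather, default_params, events=events)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_event_before_sowing_rejected(self, two_year_weather, default_params):
        events = [
            sow_event(dt.date(2000, 9, 1)),
            ManagementEvent(date=dt.date(2000, 8, 1), kind="fertilise", n_kg_ha=50.0),
        ]
        with pytest.raises(ScheduleError):
            run_simulation(two_year_weather, default_params, events=events)

    def test_zero_radiation_no_growth_beyond_seed(self, default_params):
        weather = constant_weather(120, radn=0.0)
        events = [sow_event(weather[0].date, density=200.0)]
        daily, _, sim = run_simulation(weather, default_params, events=events)
        seed_dm_kg_ha = 200.0 * 1.7e-3 * 10  # density x seed weight
        total = (
            daily.iloc[-1][[f"{o.value}_live_kg_ha" for o in Organ]].sum()
            + daily.iloc[-1][[f"{o.value}_dead_kg_ha" for o in Organ]].sum()
        )
        assert total <= seed_dm_kg_ha + 1e-9
        assert sim.balance.production == 0.0

    def test_defoliation_does_not_change_phase(self, default_params):
        weather = constant_weather(150)
        cut_day = weather[100].date
        events = [sow_event(weather[0].date)]
        d0, _, _ = run_simulation(weather, default_params, events=events)
        events_cut = events + [
            ManagementEvent(date=cut_day, kind="defoliate", fraction=0.8)
        ]
        d1, _, _ = run_simulation(weather, default_params, events=events_cut)
        assert (d0["phase"] == d1["phase"]).all()

    def test_two_year_run_closures_and_bounds(self, two_year_weather, default_params):
        """Whole-run mass, N and water closure plus Table-like N bounds."""
        events = [sow_event(dt.date(2000, 9, 1))]
        for m in range(15):  # monthly cuts Oct 2000 .. Dec 2001
            date = dt.date(2000, 10, 1) + pd.DateOffset(months=m)
            events.append(ManagementEvent(date=date.date(), kind="defoliate",
                                          residual_height_mm=70.0))
            events.append(ManagementEvent(date=(date + pd.Timedelta(days=1)).date(),
                                          kind="fertilise", n_kg_ha=20.0))
        events.append(ManagementEvent(date=dt.date(2001, 1, 5), kind="irrigate",
                                      water_mm=30.0))
        daily, harv, sim = run_simulation(two_year_weather, default_params, events=events)
        assert sim.dm_closure_error() < 1e-6
        assert sim.n_closure_error() < 1e-9
        assert sim.soil_n_closure_error() < 1e-9
        assert sim.water_closure_error() < 1e-9
        th = default_params.arbitrator.n_thresholds
        grown = daily[daily["leaf_live_kg_ha"] > 1.0]
        for o in Organ:
            conc = grown[grown[f"{o.value}_live_kg_ha"] > 1e-6][f"{o.value}_n_conc"]
            assert (conc >= th[o].n_min - 1e-9).all(), o
            assert (conc <= th[o].n_max + 1e-9).all(), o
        assert not harv.empty

    def test_height_trigger_rule_cuts_at_threshold(self, two_year_weather):
        params = SimulationParams(
            latitude=LATITUDE,
            defoliation_rule=DefoliationRule(trigger_height_mm=250.0,
                                             residual_height_mm=70.0),
        )
        events = [sow_event(dt.date(2000, 9, 1))]
        for m in range(15):  # keep N non-limiting so the sward keeps regrowing
            date = (dt.date(2000, 10, 1) + pd.DateOffset(months=m)).date()
            events.append(ManagementEvent(date=date, kind="fertilise", n_kg_ha=30.0))
        daily, harv, _ = run_simulation(two_year_weather, params, events=events)
        assert len(harv) >= 2
        assert daily["height_mm"].max() < 300.0  # never far past the trigger


class TestBehaviouralDirections:
    def test_shoot_root_ratio_recovers_after_defoliation(self, default_params):
        """Half the leaf removed: shoot:root drops, then climbs back toward
        the vegetative target under favourable conditions."""
        weather = constant_weather(240)
        cut_day = weather[150].date
        events = [
            sow_event(weather[0].date),
            ManagementEvent(date=cut_day, kind="defoliate",
                            fractions={Organ.LEAF: 0.5}),
        ]
        daily, _, _ = run_simulation(weather, default_params, events=events)
        daily = daily.set_index("date")
        shoot = sum(daily[f"{o.value}_live_kg_ha"]
                    for o in (Organ.LEAF, Organ.STEM, Organ.INFLORESCENCE))
        below = daily["taproot_live_kg_ha"] + daily["root_live_kg_ha"]
        ratio = shoot / below
        before = ratio.loc[cut_day - dt.timedelta(days=1)]
        after = ratio.loc[cut_day]
        final = ratio.iloc[-1]
        assert after < before
        assert final > after  # recovery toward the target
        assert abs(final - 2.5) < abs(after - 2.5)

    def test_water_deficit_reduces_growth(self, default_params):
        # shallow profile so the dry treatment exhausts stored water
        def shallow():
            return default_profile(n_layers=2, layer_thickness=150.0)

        dry = constant_weather(200, rain=0.0, maxt=28.0, mint=14.0)
        wet = constant_weather(200, rain=5.0, maxt=28.0, mint=14.0)
        events = [sow_event(dry[0].date)]
        d_dry, _, sim_dry = run_simulation(dry, default_params, shallow(), events)
        d_wet, _, sim_wet = run_simulation(wet, default_params, shallow(), events)
        assert sim_dry.balance.production < 0.7 * sim_wet.balance.production
        assert (d_dry["fw"].dropna() < 1.0).any()
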