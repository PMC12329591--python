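import pytest
from hypothesis import given
from hypothesis import strategies as st

from plantainforage import (
    ArbitratorParams,
    Organ,
    allocate_growth,
    allocation_fraction,
    current_targets,
    n_partition,
    retranslocate,
)
from plantainforage.arbitrator import (
    AllocationTargets,
    apply_dm_increments,
    n_demand,
    new_pools,
)
from plantainforage.phenology import Phase, PhenologyState


def make_pools(leaf=100.0, stem=0.0, infl=0.0, taproot=30.0, root=50.0):
    pools = new_pools()
    thresholds = ArbitratorParams().n_thresholds
    for organ, dm in [(Organ.LEAF, leaf), (Organ.STEM, stem),
                      (Organ.INFLORESCENCE, infl), (Organ.TAPROOT, taproot),
                      (Organ.ROOT, root)]:
        pools[organ].dm_structural = dm
        pools[organ].n_live = dm * thresholds[organ].n_crit
    return pools


def veg_state():
    s = PhenologyState()
    s.phase = Phase.VEGETATIVE
    return s


def rep_state():
    s = PhenologyState()
    s.phase = Phase.REPRODUCTIVE
    return s


class TestAllocationFraction:
    def test_empty_numerator_gets_everything(self):
        assert allocation_fraction(2.5, 0.0) == 1.0

    def test_printed_reproductive_example(self):
        # target 3.5, current 3.5: 12.25 / 15.75
        assert allocation_fraction(3.5, 3.5) == pytest.approx(12.25 / 15.75)
        assert allocation_fraction(3.5, 3.5) == pytest.approx(0.7778, abs=1e-4)

    def test_printed_vegetative_example(self):
        assert allocation_fraction(2.5, 2.5) == pytest.approx(6.25 / 8.75)
        assert allocation_fraction(2.5, 2.5) == pytest.approx(0.7143, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            allocation_fraction(0.0, 1.0)

    @given(st.floats(min_value=0.1, max_value=10, allow_nan=False),
           st.floats(min_value=0, max_value=50, allow_nan=False))
    def test_in_unit_interval_and_decreasing(self, target, current):
        p = allocation_fraction(target, current)
        assert 0.0 < p <= 1.0
        assert allocation_fraction(target, current + 1.0) < p


class TestCurrentTargets:
    def test_vegetative_forbids_reproductive_organs(self):
        t = current_targets(veg_state(), 13.0, 0.02, 1.0)
        assert t.r_sr_target == 2.5
        assert t.r_rep_leaf_target == 0.0
        inc = allocate_growth(10.0, make_pools(stem=5.0, infl=5.0), t)
        assert inc[Organ.STEM] == 0.0
        assert inc[Organ.INFLORESCENCE] == 0.0

    def test_reproductive_peak_target(self):
        t = current_targets(rep_state(), 15.0, 0.0, 1.0)
        assert t.r_sr_target == pytest.approx(3.5)

    def test_taproot_priority_in_autumn(self):
        # decreasing photoperiod raises the taproot share, all else equal
        autumn = current_targets(rep_state(), 13.0, -0.03, 5.0)
        spring = current_targets(rep_state(), 13.0, +0.03, 5.0)
        assert autumn.r_tap_root_target > spring.r_tap_root_target
        pools = make_pools()
        inc_a = allocate_growth(10.0, pools, autumn)
        inc_s = allocate_growth(10.0, pools, spring)
        share_a = inc_a[Organ.TAPROOT] / (inc_a[Organ.TAPROOT] + inc_a[Organ.ROOT])
        share_s = inc_s[Organ.TAPROOT] / (inc_s[Organ.TAPROOT] + inc_s[Organ.ROOT])
        assert share_a > share_s

    def test_taproot_priority_grows_with_plant_size(self):
        small = current_targets(veg_state(), 13.0, 0.0, 1.0)
        large = current_targets(veg_state(), 13.0, 0.0, 15.0)
        assert large.r_tap_root_target > small.r_tap_root_target


class TestAllocateGrowth:
    def test_zero_growth_zero_increments(self):
        inc = allocate_growth(0.0, make_pools(), AllocationTargets(2.5, 0.0, 0.0, 1.0))
        assert all(v == 0.0 for v in inc.values())

    @given(
        st.floats(min_value=0, max_value=50, allow_nan=False),
        st.floats(min_value=0.1, max_value=500, allow_nan=False),
        st.floats(min_value=0.1, max_value=500, allow_nan=False),
        st.floats(min_value=0, max_value=200, allow_nan=False),
        st.floats(min_value=0.5, max_value=5, allow_nan=False),
    )
    def test_conservation_and_nonnegativity(self, new_dm, leaf, root, stem, sr):
        pools = make_pools(leaf=leaf, stem=stem, taproot=root / 2, root=root)
        targets = AllocationTargets(sr, 0.3, 1.0, 1.2)
        inc = allocate_growth(new_dm, pools, targets)
        assert all(v >= 0 for v in inc.values())
        assert sum(inc.values()) == pytest.approx(new_dm, abs=1e-9 * max(1, new_dm))

    def test_ratio_converges_to_target_monotonically(self):
        # fixed-point oracle: daily growth pushes shoot:root toward 2.5
        pools = make_pools(leaf=50.0, taproot=20.0, root=30.0)  # ratio 1.0
        targets = AllocationTargets(2.5, 0.0, 0.0, 1.0)
        prev_gap = None
        for _ in range(300):
            inc = allocate_growth(5.0, pools, targets)
            apply_dm_increments(pools, inc)
            shoot = sum(pools[o].dm_live for o in (Organ.LEAF, Organ.STEM, Organ.INFLORESCENCE))
            below = pools[Organ.TAPROOT].dm_live + pools[Organ.ROOT].dm_live
            gap = abs(shoot / below - 2.5)
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-9
            prev_gap = gap
        assert prev_gap < 0.05


class TestRetranslocation:
    def test_winter_gate_closed(self):
        pools = make_pools(taproot=100.0)
        pools[Organ.TAPROOT].dm_nonstructural = 40.0
        res = retranslocate(pools, 0.0, 10.0, 1.0)
        assert res.dm == 0.0 and res.n_luxury == 0.0

    def test_reserve_cap_arithmetic(self):
        # 100 g taproot with structural fraction 0.6 -> 40 g reserve,
        # max daily transfer 4 g at full photoperiod factor
        pools = new_pools()
        pools[Organ.TAPROOT].dm_structural = 60.0
        pools[Organ.TAPROOT].dm_nonstructural = 40.0
        pools[Organ.TAPROOT].n_live = 2.0
        res = retranslocate(pools, 1.0, shortfall_dm=100.0, shortfall_n=0.0)
        assert res.dm == pytest.approx(4.0)
        assert pools[Organ.TAPROOT].dm_nonstructural == pytest.approx(36.0)

    def test_demand_limited_transfer(self):
        pools = new_pools()
        pools[Organ.TAPROOT].dm_structural = 60.0
        pools[Organ.TAPROOT].dm_nonstructural = 40.0
        pools[Organ.TAPROOT].n_live = 2.0
        res = retranslocate(pools, 1.0, shortfall_dm=1.0, shortfall_n=0.0)
        assert res.dm == pytest.approx(1.0)

    def test_luxury_n_cap(self):
        pools = new_pools()
        pools[Organ.TAPROOT].dm_structural = 100.0
        pools[Organ.TAPROOT].n_live = 2.0  # n_min share is 0.5
        res = retranslocate(pools, 1.0, 0.0, shortfall_n=10.0)
        assert res.n_luxury == pytest.approx(0.1 * (2.0 - 0.5))
        assert pools[Organ.TAPROOT].n_live >= 0.5


class TestNPartition:
    def test_structural_demand_arithmetic(self):
        # 10 g leaf increment at critical 0.035 -> 0.35 g N structural demand
        pools = new_pools()
        inc = {Organ.LEAF: 10.0}
        assert n_demand(pools, inc) >= 0.35
        res = n_partition(pools, inc, n_supply=0.35)
        assert res.n_increments[Organ.LEAF] == pytest.approx(0.35)
        assert res.growth_scale == 1.0

    def test_ample_supply_reaches_critical_everywhere(self):
        pools = make_pools()
        inc = {o: 5.0 for o in Organ}
        res = n_partition(pools, inc, n_supply=10.0)
        params = ArbitratorParams()
        for o in Organ:
            assert res.n_increments[o] >= 5.0 * params.n_thresholds[o].n_crit - 1e-12

    def test_zero_supply_scales_growth_to_zero(self):
        pools = new_pools()
        res = n_partition(pools, {Organ.LEAF: 10.0}, n_supply=0.0)
        assert res.growth_scale == 0.0

    def test_concentrations_stay_within_bounds(self):
        params = ArbitratorParams()
        pools = make_pools()
        inc = {o: 8.0 for o in Organ}
        res = n_partition(pools, inc, n_supply=100.0, params=params)  # luxury excess
        for o in Organ:
            th = params.n_thresholds[o]
            dm_new = pools[o].dm_live + inc[o]
            n_new = pools[o].n_live + res.n_increments[o]
            assert n_new / dm_new <= th.n_max + 1e-9

    def test_partition_never_creates_nitrogen(self):
        pools = make_pools()
        inc = {o: 3.0 for o in Organ}
        for supply in (0.0, 0.1, 0.5, 2.0, 50.0):
            res = n_partition(pools, inc, n_supply=supply)
            assert res.n_used <= supply + 1e-12
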