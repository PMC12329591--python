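"""Organ pools and the biomass/nitrogen arbitration.

Five organs (leaf, stem, inflorescence, taproot, root) each hold live dry
matter in structural / non-structural / metabolic pools plus a dead pool,
and live/dead nitrogen.  Daily new biomass is split hierarchically —
shoot vs root, then leaf vs reproductive organs, then stem vs
inflorescence, and taproot vs root below ground — with each split driven
by a target-to-current biomass ratio rule:

    p = r_target^2 / (r_target^2 + r_current)

which allocates everything to the lagging side of the pair and has the
target ratio as its fixed point.  Targets shift with phenology and
photoperiod: shoot:root rises from 2.5 toward 3.5 through the
reproductive phase; stems are favoured while the photoperiod is still
increasing and inflorescence later, when it decreases; the taproot gains
priority over fine roots in autumn and in larger plants.  The taproot's
non-structural pool (40 % of its biomass by default) can be
retranslocated to support regrowth, gated by a photoperiod factor.
Nitrogen allocation respects per-organ minimum / critical / maximum
concentration thresholds, with luxury uptake above critical when soil N
allows and growth down-scaled when even the minimum cannot be met.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

from .curves import PiecewiseLinear, curve_field
from .phenology import Phase, PhenologyState


class Organ(str, Enum):
    LEAF = "leaf"
    STEM = "stem"
    INFLORESCENCE = "inflorescence"
    TAPROOT = "taproot"
    ROOT = "root"


ABOVE_GROUND = (Organ.LEAF, Organ.STEM, Organ.INFLORESCENCE)
BELOW_GROUND = (Organ.TAPROOT, Organ.ROOT)


@dataclass
class OrganPool:
    """Dry matter and N of one organ (g/m2 ground area)."""

    organ: Organ
    dm_structural: float = 0.0
    dm_nonstructural: float = 0.0
    dm_metabolic: float = 0.0  # carried for fidelity; zero by default
    dm_dead: float = 0.0
    n_live: float = 0.0
    n_dead: float = 0.0

    @property
    def dm_live(self) -> float:
        return self.dm_structural + self.dm_nonstructural + self.dm_metabolic

    @property
    def n_conc(self) -> float:
        """Live N concentration (g N / g DM); 0 for an empty organ."""
        dm = self.dm_live
        return self.n_live / dm if dm > 0 else 0.0

    def check_nonnegative(self) -> None:
        for name in ("dm_structural", "dm_nonstructural", "dm_metabolic",
                     "dm_dead", "n_live", "n_dead"):
            v = getattr(self, name)
            if v < -1e-12:
                raise ValueError(f"{self.organ.value}.{name} negative: {v}")
            if v < 0:
                setattr(self, name, 0.0)


def new_pools() -> dict[Organ, OrganPool]:
    return {o: OrganPool(organ=o) for o in Organ}


@dataclass(frozen=True)
class NThresholds:
    """Minimum / critical / maximum N concentration (g N / g DM)."""

    n_min: float
    n_crit: float
    n_max: float

    def __post_init__(self) -> None:
        if not self.n_min <= self.n_crit <= self.n_max:
            raise ValueError(f"require n_min <= n_crit <= n_max, got {self}")


DEFAULT_N_THRESHOLDS: dict[Organ, NThresholds] = {
    Organ.LEAF: NThresholds(0.023, 0.035, 0.050),
    Organ.STEM: NThresholds(0.005, 0.025, 0.025),
    Organ.INFLORESCENCE: NThresholds(0.025, 0.035, 0.035),
    Organ.TAPROOT: NThresholds(0.005, 0.020, 0.020),
    Organ.ROOT: NThresholds(0.005, 0.015, 0.015),
}


@dataclass(frozen=True)
class ArbitratorParams:
    """Target ratios, their modifier curves and retranslocation constants."""

    sr_target_vegetative: float = 2.5  # shoot:root target outside the reproductive phase
    sr_target_reproductive_max: float = 3.5  # peak shoot:root target
    # 0..1 ramp of the shoot:root target with photoperiod (reproductive phase)
    sr_ramp_curve: PiecewiseLinear = curve_field([[11.5, 0.0], [14.5, 1.0]])
    rep_leaf_target: float = 0.25  # (stem+inflorescence):leaf target, reproductive phase
    infl_stem_target_base: float = 1.0
    # modifier on the inflorescence:stem target vs photoperiod change (h/day):
    # stems favoured while days lengthen, inflorescence once they shorten
    infl_stem_dpp_curve: PiecewiseLinear = curve_field([[-0.05, 2.0], [0.0, 1.0], [0.05, 0.5]])
    tap_root_target_base: float = 1.0
    tap_root_dpp_curve: PiecewiseLinear = curve_field([[-0.05, 1.5], [0.0, 1.0], [0.05, 0.75]])
    # taproot priority grows with plant size (x = g DM per plant)
    tap_root_size_curve: PiecewiseLinear = curve_field([[0.0, 0.5], [5.0, 1.0], [20.0, 1.5]])
    structural_fraction_taproot: float = 0.6  # rest is retranslocatable reserve
    dm_retranslocation_factor: float = 0.1  # max fraction of reserve moved per day
    n_retranslocation_factor: float = 0.1  # max fraction of luxury N moved per day
    # photoperiod gate on taproot retranslocation (closed in winter)
    retrans_pp_curve: PiecewiseLinear = curve_field([[10.0, 0.0], [12.0, 1.0]])
    n_thresholds: Mapping[Organ, NThresholds] = field(
        default_factory=lambda: dict(DEFAULT_N_THRESHOLDS)
    )


@dataclass(frozen=True)
class AllocationTargets:
    """Resolved target ratios for one day's arbitration."""

    r_sr_target: float  # shoot:root
    r_rep_leaf_target: float  # (stem+infl):leaf; 0 forbids reproductive growth
    r_infl_stem_target: float
    r_tap_root_target: float


def allocation_fraction(r_target: float, r_current: float) -> float:
    """Fraction of a pair's new biomass for the numerator side.

    p = r_target^2 / (r_target^2 + r_current): 1 when the numerator pool is
    empty, decreasing in the current ratio, with the target as fixed point.
    """
    if r_target <= 0:
        raise ValueError(f"r_target must be > 0, got {r_target}")
    if r_current < 0:
        raise ValueError(f"r_current must be >= 0, got {r_current}")
    t2 = r_target * r_target
    return t2 / (t2 + r_current)


def _pair_fraction(r_target: float, numer_dm: float, denom_dm: float) -> float:
    """allocation_fraction with the degenerate denominators handled:
    target 0 sends nothing to the numerator side; an empty denominator pool
    sends everything to it (current ratio -> infinity limit)."""
    if r_target <= 0:
        return 0.0
    if denom_dm <= 0:
        return 1.0 if numer_dm <= 0 else 0.0
    return allocation_fraction(r_target, numer_dm / denom_dm)


def current_targets(
    phenology: PhenologyState,
    photoperiod_h: float,
    d_photoperiod: float,
    plant_dm_per_plant: float,
    params: ArbitratorParams | None = None,
) -> AllocationTargets:
    """Resolve the day's target ratios from phenology and photoperiod.

    During the vegetative phase only leaf, taproot and root may grow
    (reproductive targets are zero); during the reproductive phase the
    shoot:root target ramps from 2.5 toward 3.5 with photoperiod, reverting
    as days shorten in autumn.
    """
    p = params or ArbitratorParams()
    reproductive = phenology.phase is Phase.REPRODUCTIVE
    if reproductive:
        ramp = min(1.0, max(0.0, p.sr_ramp_curve(photoperiod_h)))
        r_sr = p.sr_target_vegetative + ramp * (
            p.sr_target_reproductive_max - p.sr_target_vegetative
        )
        r_rep_leaf = p.rep_leaf_target
        r_infl_stem = p.infl_stem_target_base * p.infl_stem_dpp_curve(d_photoperiod)
    else:
        r_sr = p.sr_target_vegetative
        r_rep_leaf = 0.0
        r_infl_stem = 0.0
    r_tap_root = (
        p.tap_root_target_base
        * p.tap_root_dpp_curve(d_photoperiod)
        * p.tap_root_size_curve(max(0.0, plant_dm_per_plant))
    )
    return AllocationTargets(
        r_sr_target=r_sr,
        r_rep_leaf_target=r_rep_leaf,
        r_infl_stem_target=r_infl_stem,
        r_tap_root_target=r_tap_root,
    )


def allocate_growth(
    new_dm: float,
    pools: Mapping[Organ, OrganPool],
    targets: AllocationTargets,
) -> dict[Organ, float]:
    """Split ``new_dm`` (g/m2) among organs; increments sum to ``new_dm``."""
    if new_dm < 0:
        raise ValueError("new_dm must be >= 0")
    shoot = sum(pools[o].dm_live for o in ABOVE_GROUND)
    below = sum(pools[o].dm_live for o in BELOW_GROUND)
    p_shoot = _pair_fraction(targets.r_sr_target, shoot, below)
    shoot_dm = p_shoot * new_dm
    below_dm = new_dm - shoot_dm

    rep = pools[Organ.STEM].dm_live + pools[Organ.INFLORESCENCE].dm_live
    p_rep = _pair_fraction(targets.r_rep_leaf_target, rep, pools[Organ.LEAF].dm_live)
    rep_dm = p_rep * shoot_dm
    leaf_dm = shoot_dm - rep_dm

    p_infl = _pair_fraction(
        targets.r_infl_stem_target,
        pools[Organ.INFLORESCENCE].dm_live,
        pools[Organ.STEM].dm_live,
    )
    infl_dm = p_infl * rep_dm
    stem_dm = rep_dm - infl_dm

    p_tap = _pair_fraction(
        targets.r_tap_root_target,
        pools[Organ.TAPROOT].dm_live,
        pools[Organ.ROOT].dm_live,
    )
    tap_dm = p_tap * below_dm
    root_dm = below_dm - tap_dm

    return {
        Organ.LEAF: leaf_dm,
        Organ.STEM: stem_dm,
        Organ.INFLORESCENCE: infl_dm,
        Organ.TAPROOT: tap_dm,
        Organ.ROOT: root_dm,
    }


def apply_dm_increments(
    pools: dict[Organ, OrganPool],
    increments: Mapping[Organ, float],
    params: ArbitratorParams | None = None,
) -> None:
    """Add allocated DM to live pools; taproot splits off its reserve fraction."""
    p = params or ArbitratorParams()
    for organ, inc in increments.items():
        pool = pools[organ]
        if organ is Organ.TAPROOT:
            pool.dm_structural += inc * p.structural_fraction_taproot
            pool.dm_nonstructural += inc * (1.0 - p.structural_fraction_taproot)
        else:
            pool.dm_structural += inc


@dataclass
class RetranslocationResult:
    dm: float = 0.0  # DM moved out of the taproot reserve, g/m2
    n_carried: float = 0.0  # N carried with that DM (at taproot concentration)
    n_luxury: float = 0.0  # luxury N mobilised above the taproot minimum


def retranslocate(
    pools: dict[Organ, OrganPool],
    photoperiod_factor: float,
    shortfall_dm: float,
    shortfall_n: float,
    params: ArbitratorParams | None = None,
) -> RetranslocationResult:
    """Mobilise taproot reserves to cover growth shortfalls (mutates pools).

    At most ``dm_retranslocation_factor`` of the taproot non-structural DM
    and ``n_retranslocation_factor`` of its N above the minimum
    concentration move per day, scaled by the photoperiod gate and capped
    by the shortfalls.  Retranslocated DM carries its share of taproot N.
    """
    if shortfall_dm < 0 or shortfall_n < 0:
        raise ValueError("shortfalls must be >= 0")
    p = params or ArbitratorParams()
    f = min(1.0, max(0.0, photoperiod_factor))
    tap = pools[Organ.TAPROOT]
    res = RetranslocationResult()
    if f <= 0:
        return res

    dm_cap = p.dm_retranslocation_factor * tap.dm_nonstructural * f
    res.dm = min(shortfall_dm, dm_cap)
    if res.dm > 0:
        conc = tap.n_conc
        tap.dm_nonstructural -= res.dm
        res.n_carried = conc * res.dm
        tap.n_live -= res.n_carried

    n_min = p.n_thresholds[Organ.TAPROOT].n_min
    luxury = max(0.0, tap.n_live - n_min * tap.dm_live)
    n_cap = p.n_retranslocation_factor * luxury * f
    res.n_luxury = min(shortfall_n, n_cap)
    tap.n_live -= res.n_luxury
    tap.check_nonnegative()
    return res


@dataclass
class NPartitionResult:
    n_increments: dict[Organ, float]
    growth_scale: float  # 1 unless growth was N-limited below minimum concentration
    n_stress_ratio: float  # supply / structural demand (capped at 1)
    n_used: float  # total N actually fixed into live pools


def n_demand(
    pools: Mapping[Organ, OrganPool],
    increments: Mapping[Organ, float],
    params: ArbitratorParams | None = None,
) -> float:
    """Total plant N demand: structural (critical conc of new tissue) plus
    luxury (topping all live tissue up to maximum conc)."""
    p = params or ArbitratorParams()
    total = 0.0
    for organ, inc in increments.items():
        th = p.n_thresholds[organ]
        pool = pools[organ]
        total += inc * th.n_crit
        total += max(0.0, (pool.dm_live + inc) * th.n_max - (pool.n_live + inc * th.n_crit))
    return total


def n_partition(
    pools: Mapping[Organ, OrganPool],
    increments: Mapping[Organ, float],
    n_supply: float,
    params: ArbitratorParams | None = None,
) -> NPartitionResult:
    """Distribute available N to the organs' new growth.

    Priority: minimum concentration of new tissue first (growth is scaled
    down if even this cannot be met), then up to critical pro-rata, then
    luxury toward the maximum pro-rata.  Concentrations stay inside
    [n_min, n_max] afterwards.
    """
    if n_supply < 0:
        raise ValueError("n_supply must be >= 0")
    p = params or ArbitratorParams()
    th = p.n_thresholds
    organs = list(increments)
    inc = {o: max(0.0, increments[o]) for o in organs}

    min_d = {o: inc[o] * th[o].n_min for o in organs}
    total_min = sum(min_d.values())
    scale = 1.0
    if total_min > n_supply:
        scale = n_supply / total_min if total_min > 0 else 0.0
        inc = {o: v * scale for o, v in inc.items()}
        min_d = {o: v * scale for o, v in min_d.items()}
        total_min = sum(min_d.values())

    n_inc = dict(min_d)
    remaining = n_supply - total_min

    crit_d = {o: inc[o] * (th[o].n_crit - th[o].n_min) for o in organs}
    total_crit = sum(crit_d.values())
    structural_total = total_min + total_crit
    take = min(remaining, total_crit)
    if total_crit > 0 and take > 0:
        for o in organs:
            n_inc[o] += take * crit_d[o] / total_crit
        remaining -= take

    if remaining > 0:
        lux_d = {
            o: max(
                0.0,
                (pools[o].dm_live + inc[o]) * th[o].n_max - (pools[o].n_live + n_inc[o]),
            )
            for o in organs
        }
        total_lux = sum(lux_d.values())
        take = min(remaining, total_lux)
        if total_lux > 0 and take > 0:
            for o in organs:
                n_inc[o] += take * lux_d[o] / total_lux
            remaining -= take

    stress = 1.0 if structural_total <= 0 else min(1.0, (n_supply) / structural_total)
    return NPartitionResult(
        n_increments=n_inc,
        growth_scale=scale,
        n_stress_ratio=stress,
        n_used=sum(n_inc.values()),
    )
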