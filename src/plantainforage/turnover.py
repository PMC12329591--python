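"""Senescence and detachment of plant material.

Each organ loses a reference fraction of its live biomass per day
(0.005 leaf, 0.1 stem, 0.25 inflorescence, 0.005 taproot, 0.01 root),
modulated by phenology/age, canopy cover (leaves only), temperature and
water status — modifiers start at zero for young stands and can exceed
one.  Above-ground senesced material joins the organ's dead pool;
below-ground material goes straight to a soil-organic-matter accounting
sink.  N above the organ's minimum concentration is recovered to a plant
reserve at senescence; the dead material carries the minimum
concentration.  Dead above-ground material later detaches to a
surface-residue sink at a rate that slows in dry soil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .arbitrator import ABOVE_GROUND, DEFAULT_N_THRESHOLDS, NThresholds, Organ, OrganPool
from .curves import PiecewiseLinear, curve_field
from .phenology import Phase, PhenologyState


@dataclass(frozen=True)
class TurnoverParams:
    # reference daily senescence fractions per organ
    senescence_ref: Mapping[Organ, float] = field(
        default_factory=lambda: {
            Organ.LEAF: 0.005,
            Organ.STEM: 0.1,
            Organ.INFLORESCENCE: 0.25,
            Organ.TAPROOT: 0.005,
            Organ.ROOT: 0.01,
        }
    )
    # reference daily detachment fractions of dead above-ground pools
    detachment_ref: Mapping[Organ, float] = field(
        default_factory=lambda: {
            Organ.LEAF: 0.05,
            Organ.STEM: 0.03,
            Organ.INFLORESCENCE: 0.03,
        }
    )
    # age ramp of the phenology modifier (x = days since emergence)
    fpheno_age_curve: PiecewiseLinear = curve_field([[0.0, 0.5], [60.0, 1.0]])
    # extra turnover in the reproductive phase
    fpheno_reproductive_leaf: float = 1.5
    fpheno_reproductive_other: float = 2.0
    # cover effect on leaf turnover (resource competition at high cover)
    fcover_curve: PiecewiseLinear = curve_field([[0.0, 1.0], [0.7, 1.0], [0.95, 1.5], [0.99, 2.0]])
    # air temperature effect, above-ground organs (cold accelerates)
    ft_above_curve: PiecewiseLinear = curve_field([[-5.0, 2.0], [0.0, 1.5], [5.0, 1.0], [35.0, 1.0], [40.0, 1.5]])
    # water deficit accelerates above-ground senescence (x = supply/demand)
    fw_above_curve: PiecewiseLinear = curve_field([[0.0, 2.0], [0.5, 1.0], [1.0, 1.0]])
    # below-ground: temperature neutral, waterlogging detrimental
    ft_below_curve: PiecewiseLinear = curve_field([[0.0, 1.0], [40.0, 1.0]])
    # x = soil moisture status (0 wilting point, 1 field capacity, 2 saturation)
    fw_below_curve: PiecewiseLinear = curve_field([[0.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
    # detachment moisture factor on the same moisture-status axis
    detach_moisture_curve: PiecewiseLinear = curve_field([[0.0, 0.0], [1.0, 1.0], [2.0, 1.5]])
    n_thresholds: Mapping[Organ, NThresholds] = field(
        default_factory=lambda: dict(DEFAULT_N_THRESHOLDS)
    )


@dataclass
class TurnoverFluxes:
    """One day's senescence/detachment transfers (g/m2)."""

    senesced_dm: dict[Organ, float] = field(default_factory=dict)
    senesced_n_to_dead: dict[Organ, float] = field(default_factory=dict)
    n_recovered: float = 0.0  # N above minimum, returned to the plant reserve
    som_dm: float = 0.0  # below-ground senesced DM to the SOM sink
    som_n: float = 0.0
    detached_dm: float = 0.0  # dead above-ground DM to the residue sink
    detached_n: float = 0.0


def senescence_modifiers(
    phenology: PhenologyState,
    cover: float,
    tavg: float,
    water_stress_ratio: float,
    moisture_status: float,
    params: TurnoverParams | None = None,
) -> dict[Organ, float]:
    """Combined senescence modifier per organ for the day."""
    p = params or TurnoverParams()
    age_f = p.fpheno_age_curve(max(0, phenology.days_since_emergence))
    reproductive = phenology.phase is Phase.REPRODUCTIVE
    mods: dict[Organ, float] = {}
    for organ in Organ:
        if reproductive:
            phase_f = (
                p.fpheno_reproductive_leaf
                if organ is Organ.LEAF
                else p.fpheno_reproductive_other
            )
        else:
            phase_f = 1.0
        fpheno = age_f * phase_f
        if organ in ABOVE_GROUND:
            m = fpheno * p.ft_above_curve(tavg) * p.fw_above_curve(water_stress_ratio)
            if organ is Organ.LEAF:
                m *= p.fcover_curve(cover)
        else:
            m = fpheno * p.ft_below_curve(tavg) * p.fw_below_curve(moisture_status)
        mods[organ] = m
    return mods


def senesce(
    pools: dict[Organ, OrganPool],
    modifiers: Mapping[Organ, float],
    params: TurnoverParams | None = None,
) -> TurnoverFluxes:
    """Apply one day of senescence (mutates pools, returns the fluxes)."""
    p = params or TurnoverParams()
    out = TurnoverFluxes()
    for organ, pool in pools.items():
        if pool.dm_live <= 0:
            out.senesced_dm[organ] = 0.0
            continue
        mod = modifiers.get(organ, 1.0)
        if mod < 0:
            raise ValueError(f"negative senescence modifier for {organ.value}")
        frac = p.senescence_ref[organ] * mod
        if frac > 1.0:
            warnings.warn(
                f"daily senescence fraction {frac:.2f} for {organ.value} capped at 1",
                stacklevel=2,
            )
            frac = 1.0
        sen_dm = pool.dm_live * frac
        conc = pool.n_conc
        n_min = p.n_thresholds[organ].n_min
        n_to_dead = sen_dm * min(conc, n_min)
        n_recovered = sen_dm * conc - n_to_dead

        # remove proportionally across live sub-pools
        live = pool.dm_live
        for attr in ("dm_structural", "dm_nonstructural", "dm_metabolic"):
            v = getattr(pool, attr)
            setattr(pool, attr, v - sen_dm * v / live)
        pool.n_live -= sen_dm * conc
        out.n_recovered += n_recovered
        out.senesced_dm[organ] = sen_dm
        if organ in ABOVE_GROUND:
            pool.dm_dead += sen_dm
            pool.n_dead += n_to_dead
            out.senesced_n_to_dead[organ] = n_to_dead
        else:
            out.som_dm += sen_dm
            out.som_n += n_to_dead
        pool.check_nonnegative()
    return out


def detach(
    pools: dict[Organ, OrganPool],
    moisture_status: float,
    params: TurnoverParams | None = None,
) -> tuple[float, float]:
    """Move dead above-ground DM/N to the surface residue (mutates pools).

    Returns (detached_dm, detached_n) in g/m2.  The moisture factor is
    non-decreasing in soil moisture status (0 = wilting point, 1 = field
    capacity, 2 = saturation): detachment stalls in dry conditions.
    """
    p = params or TurnoverParams()
    if not 0.0 <= moisture_status <= 2.0:
        raise ValueError(f"moisture status must be in [0, 2], got {moisture_status}")
    factor = max(0.0, p.detach_moisture_curve(moisture_status))
    dm_total = n_total = 0.0
    for organ in ABOVE_GROUND:
        pool = pools[organ]
        if pool.dm_dead <= 0:
            continue
        frac = min(1.0, p.detachment_ref[organ] * factor)
        dm = pool.dm_dead * frac
        n = pool.n_dead * frac
        pool.dm_dead -= dm
        pool.n_dead -= n
        dm_total += dm
        n_total += n
        pool.check_nonnegative()
    return dm_total, n_total
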