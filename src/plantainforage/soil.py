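"""Minimal layered soil water and mineral-N bucket.

A cascading bucket: infiltration fills layers to the drained upper limit
top-down and the excess drains from the profile; soil evaporation acts on
the top layer; plant uptake cannot draw a layer below its lower limit.
Mineral N is a per-layer store fed by fertiliser only (no mineralisation
or leaching), keeping the plant's N driver fully controllable.  Root
biomass is distributed exponentially with depth down to at most one
metre, excluded from layers with a zero exploration factor (XF), and
converted to root length with a specific root length of 120 m/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class NoRootZoneError(ValueError):
    """No layer inside the rooting depth permits root growth (all XF zero)."""


@dataclass
class SoilLayer:
    depth_top: float  # mm
    depth_bottom: float  # mm
    ll: float = 0.10  # lower limit (wilting point), volumetric
    dul: float = 0.30  # drained upper limit (field capacity), volumetric
    sat: float = 0.40  # saturation, volumetric
    water: float = 0.0  # mm stored
    mineral_n: float = 0.0  # g N/m2
    xf: float = 1.0  # root exploration factor, 0..1
    kl: float = 0.08  # daily extractable fraction of available water
    root_dm: float = 0.0  # g/m2

    def __post_init__(self) -> None:
        if not self.ll < self.dul < self.sat:
            raise ValueError(f"require ll < dul < sat, got {self.ll}, {self.dul}, {self.sat}")
        if not 0.0 <= self.xf <= 1.0:
            raise ValueError(f"xf must be in [0,1], got {self.xf}")
        if self.water == 0.0:
            self.water = self.dul * self.thickness  # start at field capacity

    @property
    def thickness(self) -> float:
        return self.depth_bottom - self.depth_top

    @property
    def ll_mm(self) -> float:
        return self.ll * self.thickness

    @property
    def dul_mm(self) -> float:
        return self.dul * self.thickness

    @property
    def sat_mm(self) -> float:
        return self.sat * self.thickness

    @property
    def available_water(self) -> float:
        """Plant-available water above the lower limit (mm)."""
        return max(0.0, self.water - self.ll_mm)

    @property
    def moisture_status(self) -> float:
        """0 at wilting point, 1 at field capacity, 2 at saturation."""
        if self.water <= self.dul_mm:
            s = (self.water - self.ll_mm) / (self.dul_mm - self.ll_mm)
            return max(0.0, s)
        return 1.0 + min(1.0, (self.water - self.dul_mm) / (self.sat_mm - self.dul_mm))


@dataclass(frozen=True)
class SoilParams:
    root_front_velocity: float = 10.0  # mm/day advance of the rooting front
    max_root_depth: float = 1000.0  # mm
    specific_root_length: float = 120.0  # m root per g DM
    root_decay_depth: float = 300.0 / math.log(2.0)  # mm; 50 % decay per 300 mm
    evap_coef: float = 0.6  # fraction of bare-soil PET actually evaporated
    n_uptake_coef: float = 0.1  # max fraction of layer mineral N per day


def default_profile(
    n_layers: int = 5,
    layer_thickness: float = 200.0,
    mineral_n_total: float = 10.0,
    **layer_kwargs,
) -> list[SoilLayer]:
    """A uniform profile (default 5 x 200 mm) at field capacity, with kl
    declining with depth and mineral N concentrated near the surface."""
    kls = [0.08, 0.06, 0.04, 0.03, 0.02]
    layers = []
    weights = [0.5 ** i for i in range(n_layers)]
    wsum = sum(weights)
    for i in range(n_layers):
        layers.append(
            SoilLayer(
                depth_top=i * layer_thickness,
                depth_bottom=(i + 1) * layer_thickness,
                kl=kls[i] if i < len(kls) else kls[-1],
                mineral_n=mineral_n_total * weights[i] / wsum,
                **layer_kwargs,
            )
        )
    return layers


@dataclass
class WaterFluxes:
    infiltration: float = 0.0
    evaporation: float = 0.0
    drainage: float = 0.0
    uptake: float = 0.0


def distribute_roots(
    root_dm_total: float,
    layers: list[SoilLayer],
    root_depth: float,
    params: SoilParams | None = None,
) -> None:
    """Assign total root DM to layers (mutates ``layers``).

    Exponential decay with depth, weighted by XF and the rooted fraction
    of each layer, truncated at ``root_depth`` and renormalised so the
    layer masses sum to the total.
    """
    p = params or SoilParams()
    root_depth = min(root_depth, p.max_root_depth, layers[-1].depth_bottom)
    weights = []
    for lyr in layers:
        top = lyr.depth_top
        bottom = min(lyr.depth_bottom, root_depth)
        if bottom <= top or lyr.xf <= 0:
            weights.append(0.0)
            continue
        mid = 0.5 * (top + bottom)
        weights.append(lyr.xf * (bottom - top) * math.exp(-mid / p.root_decay_depth))
    total_w = sum(weights)
    if root_dm_total > 0 and total_w <= 0:
        raise NoRootZoneError("no rootable layer (xf > 0) within the rooting depth")
    for lyr, w in zip(layers, weights):
        lyr.root_dm = root_dm_total * w / total_w if total_w > 0 else 0.0


def root_length(layers: list[SoilLayer], params: SoilParams | None = None) -> float:
    """Total root length (m per m2 ground) over the profile."""
    p = params or SoilParams()
    return sum(lyr.root_dm for lyr in layers) * p.specific_root_length


def water_balance_step(
    layers: list[SoilLayer],
    rain: float,
    irrigation: float,
    pet: float,
    cover: float,
    uptake_per_layer: list[float] | None = None,
    params: SoilParams | None = None,
) -> WaterFluxes:
    """One day of the cascading water bucket (mutates ``layers``).

    Order: plant uptake (already resolved by :func:`supplies`), then
    infiltration cascading to the drained upper limit top-down with the
    excess leaving as drainage, then soil evaporation from the top layer
    damped by canopy cover.
    """
    if rain < 0 or irrigation < 0 or pet < 0:
        raise ValueError("fluxes must be >= 0")
    p = params or SoilParams()
    fx = WaterFluxes(infiltration=rain + irrigation)

    if uptake_per_layer is not None:
        for lyr, u in zip(layers, uptake_per_layer):
            u = min(u, lyr.available_water)
            lyr.water -= u
            fx.uptake += u

    excess = fx.infiltration
    for lyr in layers:
        room = lyr.dul_mm - lyr.water
        absorbed = min(excess, max(0.0, room))
        lyr.water += absorbed
        excess -= absorbed
    fx.drainage = excess

    top = layers[0]
    evap = min(p.evap_coef * pet * (1.0 - cover), top.available_water)
    top.water -= evap
    fx.evaporation = evap
    return fx


@dataclass
class Supplies:
    water_supply: float = 0.0  # mm/day potential
    n_supply: float = 0.0  # g N/m2/day potential
    water_uptake: list[float] = field(default_factory=list)  # per layer, actual
    n_uptake: list[float] = field(default_factory=list)  # per layer, actual

    @property
    def water_total(self) -> float:
        return sum(self.water_uptake)

    @property
    def n_total(self) -> float:
        return sum(self.n_uptake)


def supplies(
    layers: list[SoilLayer],
    water_demand: float,
    n_demand: float,
    params: SoilParams | None = None,
) -> Supplies:
    """Potential and actual uptake of water and mineral N.

    Per-layer potential water supply is kl x plant-available water in
    rooted layers; N supply is a daily extractable fraction of the layer's
    mineral N.  Actual uptake is min(demand, total potential) distributed
    pro-rata; the ratio supply/demand feeds the growth water factor.
    Mutates layer mineral N (water is drawn in :func:`water_balance_step`).
    """
    if water_demand < 0 or n_demand < 0:
        raise ValueError("demands must be >= 0")
    p = params or SoilParams()
    w_pot = [lyr.kl * lyr.available_water if lyr.root_dm > 0 else 0.0 for lyr in layers]
    n_pot = [p.n_uptake_coef * lyr.mineral_n if lyr.root_dm > 0 else 0.0 for lyr in layers]
    sup = Supplies(water_supply=sum(w_pot), n_supply=sum(n_pot))

    w_take = min(water_demand, sup.water_supply)
    sup.water_uptake = [
        w_take * w / sup.water_supply if sup.water_supply > 0 else 0.0 for w in w_pot
    ]
    n_take = min(n_demand, sup.n_supply)
    sup.n_uptake = [
        n_take * n / sup.n_supply if sup.n_supply > 0 else 0.0 for n in n_pot
    ]
    for lyr, u in zip(layers, sup.n_uptake):
        lyr.mineral_n -= u
    return sup
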