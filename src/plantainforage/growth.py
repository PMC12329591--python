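"""Daily gross biomass production: radiation-use-efficiency photosynthesis
modulated by environmental response factors.

Production = intercepted radiation x RUE x fCO2 x fN x fT x min(fW, fVPD).
RUE is on a total-solar-radiation basis (2.0 g DM/MJ for plantain).  The
min() of the two water-linked stresses avoids double-counting; a fully
multiplicative combination is available as an option.  The temperature
factor uses the day-weighted mean 0.75·Tmax + 0.25·Tmin; the N factor
responds to leaf N concentration relative to its critical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .curves import PiecewiseLinear, curve_field


@dataclass(frozen=True)
class GrowthParams:
    """RUE and the response-curve anchors (all configurable tables)."""

    rue: float = 2.0  # g DM / MJ total solar radiation
    co2_reference: float = 350.0  # ppm
    combine_water_multiplicative: bool = False
    # factor curves: x -> multiplier
    fco2_curve: PiecewiseLinear = curve_field([[0, 0.0], [350, 1.0], [700, 1.25], [2000, 1.4]])
    fn_curve: PiecewiseLinear = curve_field([[0.5, 0.0], [1.0, 1.0]])  # x = leafN/critical
    ft_curve: PiecewiseLinear = curve_field([[1, 0.0], [18, 1.0], [25, 1.0], [36, 0.0]])
    fvpd_curve: PiecewiseLinear = curve_field([[0, 1.0], [1.25, 1.0], [4.0, 0.2]])


@dataclass
class GrowthFactors:
    """Dimensionless multipliers on potential photosynthesis."""

    fco2: float = 1.0
    fn: float = 1.0
    ft: float = 1.0
    fw: float = 1.0
    fvpd: float = 1.0

    def combined(self, multiplicative_water: bool = False) -> float:
        water = (
            self.fw * self.fvpd if multiplicative_water else min(self.fw, self.fvpd)
        )
        return self.fco2 * self.fn * self.ft * water


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def growth_factors(
    co2: float,
    leaf_n_ratio: float,
    maxt: float,
    mint: float,
    water_supply: float,
    water_demand: float,
    vpd: float,
    params: GrowthParams | None = None,
) -> GrowthFactors:
    """Evaluate the five response factors from the day's state.

    ``leaf_n_ratio`` is leaf N concentration over its critical value
    (>= 1 means unrestricted); the water factor is supply/demand clamped
    to [0, 1] (1 when demand is zero).
    """
    p = params or GrowthParams()
    tw = 0.75 * maxt + 0.25 * mint
    fw = 1.0 if water_demand <= 0 else _clamp01(water_supply / water_demand)
    return GrowthFactors(
        fco2=max(0.0, p.fco2_curve(co2)),
        fn=_clamp01(p.fn_curve(leaf_n_ratio)),
        ft=_clamp01(p.ft_curve(tw)),
        fw=fw,
        fvpd=_clamp01(p.fvpd_curve(vpd)),
    )


def daily_photosynthesis(
    intercepted: float,
    factors: GrowthFactors,
    params: GrowthParams | None = None,
) -> float:
    """Gross daily production (g DM/m2) from intercepted radiation (MJ/m2)."""
    p = params or GrowthParams()
    if intercepted < 0:
        raise ValueError("intercepted radiation must be >= 0")
    return intercepted * p.rue * factors.combined(p.combine_water_multiplicative)


def potential_photosynthesis(
    intercepted: float,
    factors: GrowthFactors,
    params: GrowthParams | None = None,
) -> float:
    """Production before water limitation (used to set water demand)."""
    p = params or GrowthParams()
    return intercepted * p.rue * factors.fco2 * factors.fn * factors.ft
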