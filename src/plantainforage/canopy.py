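"""Canopy: leaf area, plant height, light interception and water demand.

Leaf biomass converts to leaf area through a fixed specific leaf area
(21 m2/kg DM), ignoring environmental variation.  Height is a saturating
function of current leaf biomass, so a defoliation that removes leaf
automatically resets height.  Light interception follows Beer's law for a
monoculture; dead leaf shades (adds to cover) but does not
photosynthesise.  Water demand uses a transpiration-efficiency closure:
the water needed to realise the day's radiation-limited potential growth
at the current vapour pressure deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CanopyParams:
    sla: float = 21.0  # m2/kg DM
    k_ext: float = 0.5  # light extinction coefficient
    h0_mm: float = 30.0  # residual (stubble) height at zero leaf biomass
    h_max_mm: float = 450.0  # asymptotic sward height
    k_height_kg_ha: float = 1500.0  # leaf biomass at half the height range
    te_coef: float = 0.005  # transpiration efficiency, kg DM·kPa / m2 / mm


@dataclass
class CanopyState:
    lai_live: float = 0.0
    lai_dead: float = 0.0
    height_mm: float = 0.0
    cover_total: float = 0.0
    cover_green: float = 0.0


def lai_from_leaf(leaf_dm_kg_ha: float, sla: float = 21.0) -> float:
    """LAI (m2/m2) from leaf dry matter (kg/ha) at specific leaf area ``sla`` (m2/kg)."""
    if leaf_dm_kg_ha < 0:
        raise ValueError("leaf biomass must be >= 0")
    return leaf_dm_kg_ha * 1e-4 * sla


def height_from_leaf(leaf_dm_kg_ha: float, params: CanopyParams | None = None) -> float:
    """Sward height (mm) as a saturating (rectangular-hyperbola) function of
    live leaf biomass; equals the base stubble height at zero leaf."""
    p = params or CanopyParams()
    if leaf_dm_kg_ha < 0:
        raise ValueError("leaf biomass must be >= 0")
    return p.h0_mm + (p.h_max_mm - p.h0_mm) * leaf_dm_kg_ha / (leaf_dm_kg_ha + p.k_height_kg_ha)


def leaf_from_height(height_mm: float, params: CanopyParams | None = None) -> float:
    """Inverse of :func:`height_from_leaf`: live leaf biomass (kg/ha) at a
    given sward height.  Heights at/below the base return 0."""
    p = params or CanopyParams()
    if height_mm >= p.h_max_mm:
        raise ValueError(f"height {height_mm} mm at/above the asymptote {p.h_max_mm} mm")
    if height_mm <= p.h0_mm:
        return 0.0
    return p.k_height_kg_ha * (height_mm - p.h0_mm) / (p.h_max_mm - height_mm)


def cover_from_lai(lai: float, k_ext: float = 0.5) -> float:
    """Fractional ground cover 1 - exp(-k·LAI) (Beer's law)."""
    return 1.0 - math.exp(-k_ext * lai)


def intercepted_radiation(radn: float, cover: float) -> float:
    """Radiation intercepted by the canopy (MJ/m2/day)."""
    if radn < 0:
        raise ValueError("radn must be >= 0")
    return radn * cover


def water_demand(
    potential_growth_g_m2: float,
    vpd_kpa: float,
    params: CanopyParams | None = None,
) -> float:
    """Crop water demand (mm/day) to realise the potential growth at the
    day's VPD, via the transpiration-efficiency coefficient."""
    p = params or CanopyParams()
    if potential_growth_g_m2 < 0 or vpd_kpa < 0:
        raise ValueError("inputs must be >= 0")
    if p.te_coef <= 0:
        raise ValueError("te_coef must be > 0")
    return (potential_growth_g_m2 / 1000.0) * vpd_kpa / p.te_coef


def update_canopy(
    leaf_dm_live_kg_ha: float,
    leaf_dm_dead_kg_ha: float,
    params: CanopyParams | None = None,
) -> CanopyState:
    """Recompute the full canopy state from current leaf pools."""
    p = params or CanopyParams()
    lai_live = lai_from_leaf(leaf_dm_live_kg_ha, p.sla)
    lai_dead = lai_from_leaf(leaf_dm_dead_kg_ha, p.sla)
    return CanopyState(
        lai_live=lai_live,
        lai_dead=lai_dead,
        height_mm=height_from_leaf(leaf_dm_live_kg_ha, p),
        cover_total=cover_from_lai(lai_live + lai_dead, p.k_ext),
        cover_green=cover_from_lai(lai_live, p.k_ext),
    )
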