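# Methods

This note documents the model equations, the daily update order, the
default parameterisation, and the design choices taken where published
information on forage plantain leaves the design open.

## Scope and structure

The package simulates a pure plantain stand at the population-average
level: five organs (leaf, stem, inflorescence, taproot, fine roots), each
holding dry matter in structural / non-structural / metabolic pools plus
a dead pool, with live and dead nitrogen. There is no population
dynamics, no explicit flower or seed development, no grazing-animal
model, and no multi-species light or water competition. Senesced
below-ground material and detached surface litter go to accounting sinks
only — no soil organic matter turnover is simulated. The metabolic DM
pool is carried in the data model for structural fidelity but stays zero:
only the taproot distinguishes structural from non-structural
(retranslocatable) biomass.

## Weather drivers

* **Thermal time** is piecewise linear in daily mean temperature
  ((T_max+T_min)/2) between three cardinal temperatures. Published data
  for plantain constrain the minimum to 0–14 °C, the optimum to just
  above 20 °C and the maximum to 30–38 °C; the defaults T_min = 1 °C,
  T_opt = 22 °C, T_max = 36 °C sit inside those ranges and are
  configurable. The peak daily accumulation defaults to T_opt − T_min
  (unit slope on the sub-optimal limb), a common crop-model convention.
* **Photoperiod** uses standard astronomical daylength with a
  configurable twilight sun angle, default −6° (civil twilight, the
  convention of the framework this model family comes from). Polar
  day/night clamp to 24/0 h.
* **VPD** is 0.75 × (saturation vapour pressure at T_max − at T_min)
  using the Tetens form, assuming air saturates at the overnight minimum.
* **PET**, when not supplied in the weather file, is a Priestley–Taylor
  equilibrium-evaporation surrogate from radiation and mean temperature.
* The **temperature for the photosynthesis factor** is the day-weighted
  mean 0.75·T_max + 0.25·T_min — deliberately distinct from the thermal
  time input.

### Synthetic weather

The generator emulates a dry temperate New Zealand climate: sinusoidal
annual cycle of mean temperature (default mean 12.1 °C, semi-amplitude
5.5 °C, warmest late January), radiation as FAO-56 extraterrestrial
radiation times a stochastic transmissivity (mean 0.55), and rainfall
from a two-state Markov chain (wet-day frequency 0.30, wet-after-wet
0.55) with exponential daily amounts calibrated so the expected annual
total matches the 650 mm target. It is deterministic under a fixed seed.
It does **not** reproduce real-weather autocorrelation of temperature
with rainfall, drought spells longer than the Markov chain implies, or
frost/heat extremes, so passing tests demonstrate internal consistency
and realistic seasonal forcing, not site-specific predictive skill.

## Phenology

Germination occurs one day after sowing provided the sowing layer holds
any plant-available water (100 % germination; users adjust sowing rate
for field establishment). Emergence completes at 15 + 10·d_S °Cd
(sowing depth d_S in mm; depths > 10 mm warn). The stand then cycles
perennially: vegetative → reproductive after 21 accumulated days with
photoperiod > 11.5 h, reproductive → vegetative after 21 accumulated
days below 11.5 h. Day counting is cumulative within the phase, not
consecutive, and counters reset at each transition; the published
description ("accumulation of days … for a few weeks") states the
threshold but not the count, so 21 days is a documented, configurable
choice. Induction and reset thresholds are separate parameters (both
11.5 h) to accommodate cultivar differences. Defoliation never changes
phase. Vernalisation is not required and not modelled.

## Canopy

LAI = leaf DM × SLA with SLA fixed at 21 m²/kg. Height is a rectangular
hyperbola of live leaf biomass, h = h₀ + (h_max−h₀)·W/(W+K_h) with
h₀ = 30 mm (stubble), h_max = 450 mm, K_h = 1500 kg/ha — a calibration
choice shaped to the saturating height-biomass relation and the
150–450 mm trigger heights used in defoliation trials, not a published
fit. Because height is a pure function of current leaf biomass it resets
automatically at defoliation, and the defoliation driver inverts it in
closed form to convert a residual height into a removal fraction. Light
interception is Beer's law with extinction coefficient 0.5 (typical
forage canopy; the source names the coefficient but not its value). Dead
leaf contributes to cover but not photosynthesis. Water demand uses a
transpiration-efficiency closure: demand = potential growth × VPD / TE
with TE = 0.005 kg DM·kPa/m²/mm, the standard C3 magnitude — a documented
stand-in for an energy-balance microclimate model.

## Growth

Production = intercepted radiation × RUE × f_CO2 × f_N × f_T ×
min(f_W, f_VPD), with RUE = 2.0 g DM/MJ of *total* solar radiation (no
PAR conversion). Combining the two water-linked stresses with min()
avoids double counting; a fully multiplicative option exists. All factor
curves are configurable piecewise-linear tables; the published curves are
not tabulated, so the defaults are documented approximations of their
shapes: f_CO2 saturating through (350 ppm, 1); f_N linear from 0 at half
the critical leaf N to 1 at critical; f_T 0 at 1 °C, 1 over 18–25 °C, 0
at 36 °C; f_W the supply/demand ratio clamped to [0, 1]; f_VPD 1 below
1.25 kPa falling to 0.2 at 4 kPa.

## Biomass partitioning

Each split uses p = r_target²/(r_target² + r_current), applied
hierarchically: shoot vs below-ground, leaf vs (stem+inflorescence),
stem vs inflorescence, and taproot vs fine root. The split order follows
the narrative of the partitioning description; it is not stated
explicitly in the source. The printed form of the rule is dimensionally
asymmetric (target squared against current unsquared); it is implemented
exactly as printed — its fixed point is still exactly the target ratio,
which the convergence tests exercise. During the vegetative phase the
reproductive targets are zero, so only leaf, taproot and root grow. The
shoot:root target is 2.5, ramping to 3.5 with photoperiod (linear from
11.5 h to 14.5 h) during the reproductive phase and reverting as days
shorten. The inflorescence:stem target is modulated by the daily change
in photoperiod so stems are favoured while days lengthen and
inflorescence afterwards; the taproot:root target rises when photoperiod
decreases (autumn reserve building) and with plant size (g DM per plant
= areal DM / sowing density), prioritising fine roots in young plants.
All modifier-curve anchors are config entries.

## Taproot reserves and retranslocation

New taproot DM is split 0.6 structural / 0.4 non-structural; up to 0.1
of the non-structural pool and 0.1 of N above the taproot minimum
concentration can move per day, gated by a photoperiod factor (0 below
10 h, 1 above 12 h) restricting retranslocation to the active season.
The DM shortfall that triggers mobilisation is the drop of today's
photosynthesis below yesterday's growth — a simple demand proxy that
activates after defoliation, when interception collapses. Retranslocated
DM carries its share of taproot N; N retranslocation additionally covers
structural N shortfalls.

## Nitrogen

Per-organ minimum / critical / maximum concentrations (g N/g DM):
leaf 0.023/0.035/0.050, stem 0.005/0.025/0.025, inflorescence
0.025/0.035/0.035, taproot 0.005/0.020/0.020, root 0.005/0.015/0.015.
New tissue demands the critical concentration; surplus supply tops
organs up toward the maximum (luxury uptake) pro-rata; deficit first
fills the minimum, then distributes toward critical pro-rata. When even
the minimum concentration of the day's new tissue cannot be met from
reserve + soil + retranslocated N, the day's production is down-scaled
(photosynthetic down-regulation) so concentrations never fall below the
minimum and mass closure is preserved; the unusable share of any
retranslocated reserve returns to the taproot. Whether luxury uptake
competes with structural demand across organs is not published;
structural-first then pro-rata luxury is the documented choice. At
senescence, N above the minimum returns to a plant reserve pool (used
before soil uptake the next day); dead material carries the minimum
concentration.

## Turnover

Reference daily senescence fractions: leaf 0.005, stem 0.1,
inflorescence 0.25, taproot 0.005, root 0.01, multiplied by a
phenology/age factor (0.5 for a young stand ramping to 1 over 60 days,
×1.5 for leaves and ×2 for other above-ground organs in the reproductive
phase), a cover factor for leaves (rising above cover 0.7), and
temperature/water factors — water deficit accelerates above-ground
senescence only, waterlogging accelerates below-ground senescence only.
The combined daily fraction is capped at 1 with a warning. Dead
above-ground material detaches to surface residue at reference rates of
0.05/day (leaf) and 0.03/day (stem, inflorescence) — not published;
documented defaults — scaled by a soil-moisture factor that is zero at
wilting point, 1 at field capacity and 1.5 at saturation, so detachment
stalls in dry conditions.

## Soil

A cascading bucket of layers (default 5 × 200 mm, LL 0.10, DUL 0.30,
SAT 0.40): infiltration fills layers to DUL top-down, the excess drains;
soil evaporation takes 0.6 × PET × (1 − cover) from the top layer; plant
uptake cannot draw below LL. Moisture status follows the convention
0 = wilting point, 1 = field capacity, 2 = saturation. Mineral N is
per-layer, fed only by fertiliser (added to the top layer) — no
mineralisation, leaching or denitrification, which keeps the plant N
driver fully controllable in experiments. Roots advance at 10 mm/day
from emergence to at most 1 m, distributed exponentially with depth
(50 % decay per 300 mm — a calibration choice), excluded from layers
with XF = 0, and converted to length at 120 m/g. Per-layer water supply
is kl × available water in rooted layers (kl 0.08 declining with depth);
N supply is 0.1/day of rooted-layer mineral N; actual uptake is
min(demand, potential) pro-rata.

## Daily update order

Weather drivers → phenology (germination, emergence, photoperiod
counters) → canopy state → root front and distribution → potential
growth (factors without water) → water demand → soil potential supply →
f_W → water-limited photosynthesis → DM retranslocation → allocation →
N demand, soil uptake, N retranslocation, N partition (with possible
growth down-scaling) → soil water balance → senescence → detachment →
management events (fertiliser to topsoil immediately; irrigation enters
the next day's infiltration) → height-trigger defoliation rule → output
row. This order is a design choice that resolves the circular
dependencies among demand, supply and growth; it is fixed and
deterministic given inputs.

## Units and reporting

Internal state is g/m² and mm; inputs and outputs use kg/ha
(= 10 × g/m²). Sowing creates seed reserves of density × 1.7 mg/seed
(inside the reported 1.5–2.0 mg/seed), allocated at emergence as 50 %
leaf, 35 % root, 15 % taproot at critical N. Harvest records accumulate
over growing seasons defined as 1 July–30 June. Goodness of fit uses
R², Nash–Sutcliffe efficiency and RMSE.

## Numerical notes and testing scale

All state updates are explicit daily Euler steps; pools are floored at
zero with a 1e-12 tolerance for float noise. Whole-run conservation
checks (DM, plant N, soil mineral N, soil water) hold to better than
1e-6 g/m² or mm over multi-year runs and are asserted in the test suite.
The test and acceptance experiments use 1–2 year simulations at daily
step (≈ 730 steps, < 1 s each) with six-treatment fertiliser sweeps and
paired wet/dry runs — small enough to run anywhere, large enough to
exercise every seasonal pathway (establishment, flowering, reset,
regrowth, reserve dynamics).

## Known limitations

Validation against the five New Zealand field trials behind the original
model is not possible from published information alone (their weather,
soil and management records are not public data in this package), so the
suite verifies analytic anchors, conservation laws and behavioural
directions rather than field-scale error statistics. The height curve,
factor-curve anchors, detachment rates and root-distribution decay are
calibration choices, flagged as such above. Real swards add weeds,
population decline after 2–3 years, grazing selectivity and excreta
returns, none of which are modelled.
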