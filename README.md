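# plantainforage

A daily time-step simulator of forage plantain (*Plantago lanceolata* L.)
growth, nitrogen dynamics and regrowth after defoliation, for agronomists
and modellers studying plantain-based pasture systems. It reproduces the
structure of an organ-based perennial forage crop model — thermal-time and
photoperiod phenology, radiation-use-efficiency photosynthesis,
target-ratio biomass partitioning among five organs, taproot reserve
retranslocation, organ N-concentration thresholds, senescence and
detachment, and cut-or-graze defoliation — over a minimal layered soil
water/mineral-N bucket, so whole multi-year rotations run standalone with
no external framework.

## Model core

Daily gross production comes from intercepted solar radiation via a
radiation use efficiency of 2.0 g DM/MJ, modulated by response factors for
CO₂, leaf N status, temperature (weighted mean 0.75·T_max + 0.25·T_min),
water supply/demand and vapour pressure deficit:

```
ΔW = I · RUE · f_CO2 · f_N · f_T · min(f_W, f_VPD)
```

New biomass is split among leaf, stem, inflorescence, taproot and fine
roots by a hierarchy of target-to-current biomass ratio rules; at each
split the fraction for the numerator pool is

```
p = r_target² / (r_target² + r_current)
```

which has the target ratio as its fixed point, so a defoliated sward
automatically prioritises leaf regrowth. The shoot:root target rises from
2.5 to 3.5 through the reproductive phase and reverts in autumn.
Phenology cycles perennially between vegetative and reproductive phases,
triggered by accumulated days with photoperiod above/below 11.5 h;
emergence requires `15 + 10·d_S` °Cd for sowing depth `d_S` (mm). Leaf
area uses a fixed specific leaf area of 21 m²/kg; roots are distributed
to 1 m depth at 120 m/g specific root length. Organ N is kept between
minimum and maximum concentration thresholds, with luxury uptake above
the critical level and recovery of N above the minimum at senescence.

## Worked example

Sow a stand in spring at 43.6°S on synthetic Canterbury-like weather, cut
monthly to a 70 mm residual, and fertilise after each cut:

```python
import datetime as dt
import pandas as pd
from plantainforage import (ManagementEvent, SimulationParams, compute_drivers,
                            run_simulation, season_accumulate, synth_weather)

weather = compute_drivers(synth_weather(latitude=-43.6, n_years=2, seed=11,
                                        start_year=2000), -43.6)
events = [ManagementEvent(date=dt.date(2000, 9, 1), kind="sow",
                          sowing_depth_mm=5.0, plant_density=200.0)]
for m in range(15):
    cut = (dt.date(2000, 10, 1) + pd.DateOffset(months=m)).date()
    events.append(ManagementEvent(date=cut, kind="defoliate", residual_height_mm=70.0))
    events.append(ManagementEvent(date=cut + dt.timedelta(days=4),
                                  kind="fertilise", n_kg_ha=20.0))

daily, harvests, sim = run_simulation(weather, SimulationParams(), events=events)
print(season_accumulate(harvests))
```

which prints the per-season (1 July–30 June) harvested yields:

```
 season    dm_kg_ha    n_kg_ha
2000/01 8466.561894 229.588185
2001/02 3758.560994 114.163580
```

about 8.5 t DM/ha and 230 kg N/ha harvested in the establishment season
under this modest fertiliser regime (240 kg N/ha/yr), with the partial
second season lower as soil N runs down. The `harvests` table holds each
cut's per-organ removal, total DM (kg/ha), N yield and N concentration of
the harvested material; `daily` holds phase, per-organ DM and N, LAI,
height, cover, the growth factors and soil water/N for every day; `sim`
exposes whole-run mass/N/water closure checks.

The same run is available from the shell:

```sh
plantainforage synth-weather --years 2 --seed 11 --out weather.met
plantainforage run config.yaml --out-dir results/
plantainforage validate predicted.csv observed.csv
```

with every model parameter exposed in the YAML config (see
`docs/methods.md` for the parameter reference and modelling choices).

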