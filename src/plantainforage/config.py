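"""Structured configuration: one YAML file driving a whole simulation.

Every model parameter (cardinal temperatures, phenology triggers, canopy
constants, response-curve anchors, organ N thresholds, soil layers,
management schedule, synthetic-climate normals) can be set from the
file; anything omitted keeps the documented default.  Curves are given
as ``[[x, y], ...]`` anchor lists, dates as ISO strings.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Any, Mapping

import yaml

from .arbitrator import ArbitratorParams, NThresholds, Organ
from .canopy import CanopyParams
from .curves import PiecewiseLinear
from .growth import GrowthParams
from .phenology import PhenologyParams
from .simulation import DefoliationRule, ManagementEvent, SimulationParams
from .soil import SoilLayer, SoilParams, default_profile
from .turnover import TurnoverParams
from .weather import CardinalTemperatures, ClimateParams, WeatherDay, read_met, synth_weather


class ConfigError(ValueError):
    pass


def _coerce(value: Any, target_type: Any) -> Any:
    if target_type is PiecewiseLinear and isinstance(value, (list, tuple)):
        return PiecewiseLinear.from_pairs(value)
    return value


def _build(cls, overrides: Mapping[str, Any] | None):
    """Instantiate a params dataclass with YAML overrides applied."""
    overrides = dict(overrides or {})
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in overrides.items():
        if key not in fields:
            raise ConfigError(f"unknown parameter {key!r} for {cls.__name__}")
        default = fields[key].default_factory() if fields[key].default_factory is not dataclasses.MISSING else fields[key].default  # type: ignore[misc]
        if isinstance(default, PiecewiseLinear) or (
            isinstance(value, list) and value and isinstance(value[0], list)
            and key.endswith("curve")
        ):
            value = PiecewiseLinear.from_pairs(value)
        kwargs[key] = value
    return cls(**kwargs)


def _build_arbitrator(overrides: Mapping[str, Any] | None) -> ArbitratorParams:
    overrides = dict(overrides or {})
    nth = overrides.pop("n_thresholds", None)
    params = _build(ArbitratorParams, overrides)
    if nth is not None:
        table = dict(params.n_thresholds)
        for organ_name, row in nth.items():
            table[Organ(organ_name)] = NThresholds(*row)
        params = dataclasses.replace(params, n_thresholds=table)
    return params


def _build_turnover(overrides: Mapping[str, Any] | None) -> TurnoverParams:
    overrides = dict(overrides or {})
    for key in ("senescence_ref", "detachment_ref"):
        if key in overrides:
            overrides[key] = {Organ(k): float(v) for k, v in overrides[key].items()}
    return _build(TurnoverParams, overrides)


@dataclasses.dataclass
class SimulationConfig:
    params: SimulationParams
    soil_layers: list[SoilLayer]
    events: list[ManagementEvent]
    weather: list[WeatherDay]

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "SimulationConfig":
        site = doc.get("site", {})
        cultivar = doc.get("cultivar", {})
        soil_doc = doc.get("soil", {})
        mgmt = doc.get("management", {})

        rule = mgmt.get("defoliation_rule")
        params = SimulationParams(
            latitude=float(site.get("latitude", -43.6)),
            co2=float(site.get("co2", 350.0)),
            seed_weight_mg=float(site.get("seed_weight_mg", 1.7)),
            cardinals=_build(CardinalTemperatures, cultivar.get("cardinals")),
            phenology=_build(PhenologyParams, cultivar.get("phenology")),
            canopy=_build(CanopyParams, cultivar.get("canopy")),
            growth=_build(GrowthParams, cultivar.get("growth")),
            arbitrator=_build_arbitrator(cultivar.get("arbitrator")),
            turnover=_build_turnover(cultivar.get("turnover")),
            soil=_build(SoilParams, soil_doc.get("params")),
            defoliation_rule=_build(DefoliationRule, rule) if rule else None,
        )

        if "layers" in soil_doc:
            layers = [_build(SoilLayer, spec) for spec in soil_doc["layers"]]
        else:
            layers = default_profile(**(soil_doc.get("default", {}) or {}))

        events = []
        for spec in mgmt.get("events", []):
            spec = dict(spec)
            date = spec.pop("date")
            if isinstance(date, str):
                date = dt.date.fromisoformat(date)
            events.append(ManagementEvent(date=date, **spec))

        wdoc = doc.get("weather", {})
        if "met_file" in wdoc:
            weather, _ = read_met(wdoc["met_file"])
        elif "synthetic" in wdoc:
            sdoc = dict(wdoc["synthetic"] or {})
            n_years = int(sdoc.pop("n_years", 2))
            seed = int(sdoc.pop("seed", 0))
            start_year = int(sdoc.pop("start_year", 2000))
            climate = _build(ClimateParams, sdoc)
            weather = synth_weather(
                params.latitude, n_years, seed, climate, start_year=start_year
            )
        else:
            raise ConfigError("weather section needs 'met_file' or 'synthetic'")
        return cls(params=params, soil_layers=layers, events=events, weather=weather)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)
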