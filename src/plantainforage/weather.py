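"""Daily weather input and derived environmental drivers.

Reads and writes APSIM-style ``.met`` text files, derives thermal time,
astronomical photoperiod and vapour pressure deficit for each day, and
provides a stochastic generator of temperate-climate weather so that full
simulations can run without any external data.

Units: radiation MJ/m2/day, temperature degC, rainfall and PET mm/day,
photoperiod hours, thermal time degC·day (degCd), VPD kPa.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class MetFormatError(ValueError):
    """Raised when a .met file is malformed (missing columns, bad rows)."""


class MetSequenceError(ValueError):
    """Raised when .met dates are not strictly increasing."""


@dataclass
class WeatherDay:
    """One day of weather with optional derived drivers.

    ``photoperiod``, ``tt``, ``vpd`` and ``pet`` stay ``None`` until
    :func:`compute_drivers` fills them in.
    """

    date: dt.date
    radn: float  # MJ/m2/day total solar radiation
    maxt: float  # degC
    mint: float  # degC
    rain: float  # mm/day
    pet: float | None = None  # mm/day
    photoperiod: float | None = None  # h
    tt: float | None = None  # degCd
    vpd: float | None = None  # kPa

    def __post_init__(self) -> None:
        if self.radn < 0:
            raise ValueError(f"radn must be >= 0, got {self.radn}")
        if self.rain < 0:
            raise ValueError(f"rain must be >= 0, got {self.rain}")
        if self.maxt < self.mint:
            raise ValueError(f"maxt ({self.maxt}) < mint ({self.mint})")

    @property
    def tavg(self) -> float:
        """Simple daily mean temperature, used for thermal time."""
        return 0.5 * (self.maxt + self.mint)

    @property
    def tweighted(self) -> float:
        """Day-weighted mean temperature used by the growth temperature factor."""
        return 0.75 * self.maxt + 0.25 * self.mint


@dataclass(frozen=True)
class CardinalTemperatures:
    """Cardinal temperatures of the thermal-time response.

    Development is zero at or below ``tmin``, rises linearly to
    ``tt_at_topt`` degCd/day at ``topt`` and falls linearly back to zero
    at ``tmax``.  Defaults sit inside the ranges reported for plantain
    (minimum 0-14 degC, optimum just above 20, maximum 30-38 degC).
    """

    tmin: float = 1.0
    topt: float = 22.0
    tmax: float = 36.0
    tt_at_topt: float | None = None  # default topt - tmin (unit sub-optimal slope)

    def __post_init__(self) -> None:
        if not (self.tmin < self.topt < self.tmax):
            raise ValueError(
                f"require tmin < topt < tmax, got {self.tmin}, {self.topt}, {self.tmax}"
            )
        if self.tt_at_topt is None:
            object.__setattr__(self, "tt_at_topt", self.topt - self.tmin)
        if self.tt_at_topt <= 0:
            raise ValueError("tt_at_topt must be > 0")


def thermal_time(tavg: float, ct: CardinalTemperatures) -> float:
    """Daily thermal time (degCd) from mean air temperature.

    Piecewise linear: zero at/below ``tmin`` and at/above ``tmax``, peaking
    at ``tt_at_topt`` at the optimum.  Continuous and non-negative.
    """
    return float(
        np.interp(
            tavg,
            [ct.tmin, ct.topt, ct.tmax],
            [0.0, ct.tt_at_topt, 0.0],
            left=0.0,
            right=0.0,
        )
    )


def photoperiod(latitude: float, day_of_year: int, twilight_angle: float = -6.0) -> float:
    """Astronomical daylength in hours.

    Standard daylength geometry with a configurable sun angle defining
    day/night; the default -6 deg (civil twilight) lengthens the day
    relative to geometric sunrise/sunset.  Polar day/night clamp to 24/0 h.
    """
    if not -90.0 < latitude < 90.0:
        raise ValueError(f"latitude must be in (-90, 90), got {latitude}")
    # solar declination (deg), Cooper-type approximation
    decl = -23.45 * math.cos(2.0 * math.pi * (day_of_year + 10) / 365.25)
    lat_r = math.radians(latitude)
    dec_r = math.radians(decl)
    alt_r = math.radians(twilight_angle)
    cos_h = (math.sin(alt_r) - math.sin(lat_r) * math.sin(dec_r)) / (
        math.cos(lat_r) * math.cos(dec_r)
    )
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


_SVP_A, _SVP_B, _SVP_C = 0.6108, 17.27, 237.3  # Tetens, kPa / degC


def svp(t: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature t (degC), Tetens form."""
    return _SVP_A * math.exp(_SVP_B * t / (t + _SVP_C))


def vpd(maxt: float, mint: float, fraction: float = 0.75) -> float:
    """Daytime vapour pressure deficit (kPa).

    Convention: a fraction (default 0.75) of the difference between
    saturation vapour pressure at the daily maximum and minimum
    temperatures, assuming the air saturates at the overnight minimum.
    Zero when ``maxt == mint``.
    """
    if maxt < mint:
        raise ValueError(f"maxt ({maxt}) < mint ({mint})")
    return max(0.0, fraction * (svp(maxt) - svp(mint)))


def _priestley_taylor_pet(radn: float, tavg: float) -> float:
    """Potential evapotranspiration (mm/day), equilibrium-evaporation surrogate."""
    s = 4098.0 * svp(tavg) / (tavg + _SVP_C) ** 2  # slope of svp curve, kPa/degC
    gamma = 0.0665  # psychrometric constant, kPa/degC
    lam = 2.45  # latent heat, MJ/kg
    net = 0.75 * radn  # crude net-radiation fraction
    return max(0.0, 1.26 * s / (s + gamma) * net / lam)


def compute_drivers(
    days: Sequence[WeatherDay],
    latitude: float,
    cardinals: CardinalTemperatures | None = None,
    twilight_angle: float = -6.0,
    vpd_fraction: float = 0.75,
) -> list[WeatherDay]:
    """Fill photoperiod, thermal time, VPD and (if absent) PET for each day."""
    ct = cardinals or CardinalTemperatures()
    out = []
    for d in days:
        doy = d.date.timetuple().tm_yday
        out.append(
            replace(
                d,
                photoperiod=photoperiod(latitude, doy, twilight_angle),
                tt=thermal_time(d.tavg, ct),
                vpd=vpd(d.maxt, d.mint, vpd_fraction),
                pet=d.pet if d.pet is not None else _priestley_taylor_pet(d.radn, d.tavg),
            )
        )
    return out


# ---------------------------------------------------------------------------
# .met reading / writing
# ---------------------------------------------------------------------------

_MANDATORY = ("year", "day", "radn", "maxt", "mint", "rain")


def read_met(path: str | Path) -> tuple[list[WeatherDay], dict[str, float]]:
    """Read an APSIM-style .met file.

    Dialect: optional ``!`` comment lines, ``name = value`` constant lines
    (latitude, tav, amp, ...), then a whitespace-delimited header line of
    column names, a units line in parentheses, and data rows.

    Returns the day records (derived fields unset) and the constants dict.
    """
    path = Path(path)
    constants: dict[str, float] = {}
    header: list[str] | None = None
    days: list[WeatherDay] = []
    prev_date: dt.date | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("!") or line.lower().startswith("[weather"):
                continue
            if header is None and "=" in line:
                name, _, value = line.partition("=")
                try:
                    constants[name.strip().lower()] = float(value.split("(")[0].split("!")[0])
                except ValueError:
                    pass
                continue
            tokens = line.split()
            if header is None:
                header = [t.lower() for t in tokens]
                missing = [c for c in _MANDATORY if c not in header]
                if missing:
                    raise MetFormatError(
                        f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
                    )
                continue
            if re.match(r"^\(", tokens[0]):  # units line
                continue
            if len(tokens) < len(header):
                raise MetFormatError(f"{path.name}: short data row: {line!r}")
            row = dict(zip(header, tokens))
            date = dt.date(int(row["year"]), 1, 1) + dt.timedelta(days=int(row["day"]) - 1)
            if prev_date is not None and date <= prev_date:
                raise MetSequenceError(
                    f"{path.name}: dates not strictly increasing at {date}"
                )
            prev_date = date
            kwargs = {}
            if "pet" in row:
                kwargs["pet"] = float(row["pet"])
            days.append(
                WeatherDay(
                    date=date,
                    radn=float(row["radn"]),
                    maxt=float(row["maxt"]),
                    mint=float(row["mint"]),
                    rain=float(row["rain"]),
                    **kwargs,
                )
            )
    if header is None:
        raise MetFormatError(f"{path.name}: no header line found")
    return days, constants


def write_met(
    path: str | Path,
    days: Iterable[WeatherDay],
    latitude: float,
    tav: float | None = None,
    amp: float | None = None,
) -> None:
    """Write day records in the .met dialect read by :func:`read_met`."""
    days = list(days)
    temps = np.array([d.tavg for d in days])
    if tav is None:
        tav = float(temps.mean())
    if amp is None:
        monthly: dict[int, list[float]] = {}
        for d in days:
            monthly.setdefault(d.date.month, []).append(d.tavg)
        means = [float(np.mean(v)) for v in monthly.values()]
        amp = max(means) - min(means) if len(means) > 1 else 0.0
    with open(path, "w") as fh:
        fh.write("! synthetic weather written by plantainforage\n")
        fh.write(f"latitude = {latitude:.2f}\n")
        fh.write(f"tav = {tav:.2f}\n")
        fh.write(f"amp = {amp:.2f}\n")
        fh.write("year day radn maxt mint rain\n")
        fh.write("() () (MJ/m^2) (oC) (oC) (mm)\n")
        for d in days:
            doy = d.date.timetuple().tm_yday
            fh.write(
                f"{d.date.year} {doy} {d.radn!r} {d.maxt!r} {d.mint!r} {d.rain!r}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateParams:
    """Normals of the synthetic temperate climate.

    Defaults emulate a dry temperate New Zealand site: annual mean air
    temperature 12.1 degC and 650 mm/yr rainfall, with the warm season in
    January (southern hemisphere).
    """

    annual_mean_temp: float = 12.1  # degC
    seasonal_amplitude: float = 5.5  # degC, half peak-to-trough of the annual cycle
    diurnal_range: float = 9.0  # degC, mean maxt - mint
    temp_noise_sd: float = 1.8  # degC day-to-day
    annual_rainfall: float = 650.0  # mm/yr
    wet_day_prob: float = 0.30  # unconditional wet-day frequency
    wet_persistence: float = 0.55  # P(wet | yesterday wet)
    transmissivity: float = 0.55  # mean fraction of extraterrestrial radiation
    warmest_doy: int = 31  # late January (southern hemisphere)


def _extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ/m2/day), FAO-56 geometry."""
    lat = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2 * math.pi * doy / 365.25)
    decl = math.radians(-23.45 * math.cos(2 * math.pi * (doy + 10) / 365.25))
    x = -math.tan(lat) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (
        24 * 60 / math.pi
        * 0.0820
        * dr
        * (ws * math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.sin(ws))
    )


def synth_weather(
    latitude: float = -43.6,
    n_years: int = 1,
    seed: int = 0,
    climate: ClimateParams | None = None,
    start_year: int = 2000,
) -> list[WeatherDay]:
    """Generate daily weather for a temperate seasonal climate.

    Sinusoidal mean temperature and clear-sky radiation envelope with
    stochastic transmissivity, plus Markov-chain rainfall occurrence with
    exponential daily amounts calibrated to the configured annual total.
    Deterministic for a fixed seed.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    cp = climate or ClimateParams()
    rng = np.random.default_rng(seed)
    start = dt.date(start_year, 1, 1)
    end = dt.date(start_year + n_years, 1, 1)
    n_days = (end - start).days

    # mean rain per wet day so that E[annual total] hits the target
    mean_wet_amount = cp.annual_rainfall / (365.25 * cp.wet_day_prob)
    p_wd = (cp.wet_day_prob * (1.0 - cp.wet_persistence)) / (1.0 - cp.wet_day_prob)

    days: list[WeatherDay] = []
    wet = rng.random() < cp.wet_day_prob
    for i in range(n_days):
        date = start + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        phase = 2 * math.pi * (doy - cp.warmest_doy) / 365.25
        tmean = cp.annual_mean_temp + cp.seasonal_amplitude * math.cos(phase)
        noise = rng.normal(0.0, cp.temp_noise_sd)
        half = 0.5 * cp.diurnal_range
        maxt = tmean + half + noise
        mint = tmean - half + noise
        tau = np.clip(rng.normal(cp.transmissivity, 0.12), 0.18, 0.78)
        radn = max(0.5, _extraterrestrial_radiation(latitude, doy) * float(tau))
        wet = bool(rng.random() < (cp.wet_persistence if wet else p_wd))
        rain = float(rng.exponential(mean_wet_amount)) if wet else 0.0
        days.append(WeatherDay(date=date, radn=radn, maxt=maxt, mint=mint, rain=rain))
    return days
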