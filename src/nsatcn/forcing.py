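"""Synthetic climate, CO₂ and N-deposition forcing for site ensembles.

The generator stands in for the gridded observational products a global
simulation would use: it produces monthly climate (temperature, precipitation,
cloud fraction, wind speed, wet days, relative humidity) with a sinusoidal
seasonal cycle plus AR(1) interannual anomalies, a smooth global CO₂
trajectory, and region-typed annual N-deposition trajectories:

``us_temperate_forest``
    persistently high plateau (deposition above the critical load throughout
    the analysis window),
``europe_forest``
    a hump peaking in the 1980s and declining below the critical load by 2009,
``asia_grassland``
    a monotone, accelerating rise far beyond the critical load by the 2000s,
``background``
    low, flat deposition.

Every output is a pure function of ``(site_spec, years, profile, seed)``:
per-site, per-variable substreams are derived from the master seed and the
site id, so adding sites never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

YEAR_MIN, YEAR_MAX = 1851, 2009

PROFILE_NAMES = ("us_temperate_forest", "europe_forest", "asia_grassland", "background")

#: Default shape parameters per deposition profile (g N m⁻² yr⁻¹ and years).
_PROFILE_DEFAULTS: dict[str, dict[str, float]] = {
    "us_temperate_forest": {
        "start_level": 0.2, "plateau_level": 1.8,
        "ramp_center": 1950.0, "ramp_width": 10.0, "noise_sigma": 0.03,
    },
    "europe_forest": {
        "start_level": 0.5, "peak_amplitude": 2.2,
        "peak_year": 1985.0, "peak_width": 15.0, "noise_sigma": 0.015,
    },
    "asia_grassland": {
        "start_level": 0.5, "rise_rate": 0.02, "rise_accel": 0.004,
        "rise_start": 1970.0, "noise_sigma": 0.2,
    },
    "background": {"start_level": 0.1, "noise_sigma": 0.03},
}


@dataclass(frozen=True, slots=True)
class NdepProfile:
    """A parameterized annual N-deposition trajectory shape.

    ``shape_params`` overrides the per-profile defaults; ``noise_sigma`` is the
    standard deviation of the mean-one multiplicative lognormal noise (for
    ``asia_grassland`` it perturbs the yearly increments, keeping the
    trajectory non-decreasing for every seed).
    """

    profile_name: str
    start_level: float | None = None
    noise_sigma: float | None = None
    shape_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.profile_name not in PROFILE_NAMES:
            raise ConfigurationError(f"unknown deposition profile {self.profile_name!r}")

    @property
    def trajectory_shape(self) -> str:
        return {
            "us_temperate_forest": "plateau",
            "europe_forest": "hump-with-1980s-peak",
            "asia_grassland": "accelerating-rise",
            "background": "flat",
        }[self.profile_name]

    def resolved(self) -> dict[str, float]:
        p = dict(_PROFILE_DEFAULTS[self.profile_name])
        p.update(self.shape_params)
        if self.start_level is not None:
            p["start_level"] = self.start_level
        if self.noise_sigma is not None:
            p["noise_sigma"] = self.noise_sigma
        return p


@dataclass(frozen=True, slots=True)
class ClimateTemplate:
    """Mean-state and variability parameters of a site's monthly climate."""

    t_mean: float            # °C annual mean
    t_amp: float             # °C seasonal half-amplitude
    p_annual: float          # mm yr⁻¹
    p_season_amp: float = 0.3
    t_trend: float = 0.02    # °C yr⁻¹ applied after trend_start
    trend_start: int = 1970
    t_anom_sigma: float = 0.6
    t_ar1: float = 0.3
    t_month_sigma: float = 0.3
    p_noise_sigma: float = 0.25
    cloud_mean: float = 0.5
    cloud_sigma: float = 0.05
    wind_mean: float = 3.0
    wind_sigma: float = 0.4
    wetdays_mean: float = 10.0
    wetdays_sigma: float = 2.0
    rh_mean: float = 70.0
    rh_sigma: float = 5.0


CLIMATE_TEMPLATES: dict[str, ClimateTemplate] = {
    "tropical forest": ClimateTemplate(25.0, 2.0, 2000.0),
    "temperate forest": ClimateTemplate(10.0, 10.0, 900.0),
    "boreal forest": ClimateTemplate(-2.0, 15.0, 500.0),
    "grassland": ClimateTemplate(12.0, 9.0, 600.0),
    "shrubland": ClimateTemplate(15.0, 8.0, 400.0),
    "savanna": ClimateTemplate(24.0, 3.0, 1000.0),
    "cropland": ClimateTemplate(12.0, 9.0, 800.0),
    "tundra/other": ClimateTemplate(-8.0, 14.0, 300.0),
}


@dataclass(slots=True)
class ForcingSeries:
    """Per-site monthly climate plus annual CO₂ and N deposition.

    Monthly arrays have shape ``(n_years, 12)``; annual arrays shape
    ``(n_years,)``. All series span the same gap-free inclusive year range.
    """

    site_id: str
    years: np.ndarray
    monthly_temperature: np.ndarray       # °C
    monthly_precipitation: np.ndarray     # mm month⁻¹
    cloud_fraction: np.ndarray            # [0, 1]
    wind_speed: np.ndarray                # m s⁻¹
    wet_days: np.ndarray                  # days month⁻¹
    relative_humidity: np.ndarray         # % [0, 100]
    co2: np.ndarray                       # ppm
    n_deposition: np.ndarray              # g N m⁻² yr⁻¹

    def validate(self) -> None:
        y = np.asarray(self.years)
        if y.size == 0:
            raise InputError("empty year range")
        if not np.array_equal(y, np.arange(y[0], y[-1] + 1)):
            raise InputError("years must be contiguous and increasing")
        n = y.size
        for name in ("monthly_temperature", "monthly_precipitation", "cloud_fraction",
                     "wind_speed", "wet_days", "relative_humidity"):
            arr = getattr(self, name)
            if arr.shape != (n, 12):
                raise InputError(f"{name} must have shape ({n}, 12), got {arr.shape}")
        for name in ("co2", "n_deposition"):
            if getattr(self, name).shape != (n,):
                raise InputError(f"{name} must have shape ({n},)")
        if (self.monthly_precipitation < 0).any() or (self.wet_days < 0).any():
            raise InputError("precipitation and wet days must be non-negative")
        if (self.n_deposition < 0).any() or (self.co2 < 0).any():
            raise InputError("CO2 and N deposition must be non-negative")
        if ((self.cloud_fraction < 0) | (self.cloud_fraction > 1)).any():
            raise InputError("cloud fraction outside [0, 1]")
        if ((self.relative_humidity < 0) | (self.relative_humidity > 100)).any():
            raise InputError("relative humidity outside [0, 100]")

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(
            self.site_id, self.years.copy(),
            self.monthly_temperature.copy(), self.monthly_precipitation.copy(),
            self.cloud_fraction.copy(), self.wind_speed.copy(), self.wet_days.copy(),
            self.relative_humidity.copy(), self.co2.copy(), self.n_deposition.copy(),
        )

    def year_index(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise InputError(f"year {year} outside series range "
                             f"{self.years[0]}–{self.years[-1]}")
        return int(year - self.years[0])

    # --- tidy-frame round trip -------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (climate, annual) tidy frames: one row per site-year-month /
        site-year."""
        n = self.years.size
        years = np.repeat(self.years, 12)
        months = np.tile(np.arange(1, 13), n)
        climate = pd.DataFrame({
            "site_id": self.site_id, "year": years, "month": months,
            "temperature": self.monthly_temperature.ravel(),
            "precipitation": self.monthly_precipitation.ravel(),
            "cloud_fraction": self.cloud_fraction.ravel(),
            "wind_speed": self.wind_speed.ravel(),
            "wet_days": self.wet_days.ravel(),
            "relative_humidity": self.relative_humidity.ravel(),
        })
        annual = pd.DataFrame({
            "site_id": self.site_id, "year": self.years,
            "co2": self.co2, "n_deposition": self.n_deposition,
        })
        return climate, annual

    @classmethod
    def from_frames(cls, climate: pd.DataFrame, annual: pd.DataFrame,
                    site_id: str) -> "ForcingSeries":
        cl = climate[climate["site_id"] == site_id].sort_values(["year", "month"])
        an = annual[annual["site_id"] == site_id].sort_values("year")
        years = an["year"].to_numpy()
        n = years.size

        def grid(col: str) -> np.ndarray:
            return cl[col].to_numpy(dtype=float).reshape(n, 12)

        out = cls(site_id, years.astype(int),
                  grid("temperature"), grid("precipitation"), grid("cloud_fraction"),
                  grid("wind_speed"), grid("wet_days"), grid("relative_humidity"),
                  an["co2"].to_numpy(dtype=float),
                  an["n_deposition"].to_numpy(dtype=float))
        out.validate()
        return out


# ---------------------------------------------------------------------------
# seeded substreams


def _rng(seed: int, site_id: str, variable: str) -> np.random.Generator:
    """Deterministic per-(seed, site, variable) generator."""
    key = [int(seed), zlib.crc32(site_id.encode()), zlib.crc32(variable.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def _lognoise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; exactly 1 when sigma == 0."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


# ---------------------------------------------------------------------------
# trajectories


def co2_trajectory(years: np.ndarray, co2_pre: float = 296.0,
                   co2_2009: float = 387.0) -> np.ndarray:
    """Smooth global CO₂ curve: flat pre-1900, accelerating ramp to 2009."""
    years = np.asarray(years, dtype=float)
    frac = np.clip((years - 1900.0) / (2009.0 - 1900.0), 0.0, None)
    return co2_pre + (co2_2009 - co2_pre) * frac**2


def generate_ndep(profile: NdepProfile, years: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Annual N deposition (g N m⁻² yr⁻¹) for one site; always ≥ 0."""
    p = profile.resolved()
    years = np.asarray(years, dtype=float)
    sigma = p["noise_sigma"]
    name = profile.profile_name
    if name == "background":
        dep = p["start_level"] * _lognoise(rng, sigma, years.size)
    elif name == "us_temperate_forest":
        ramp = 1.0 / (1.0 + np.exp(-(years - p["ramp_center"]) / p["ramp_width"]))
        base = p["start_level"] + (p["plateau_level"] - p["start_level"]) * ramp
        dep = base * _lognoise(rng, sigma, years.size)
    elif name == "europe_forest":
        base = p["start_level"] + p["peak_amplitude"] * np.exp(
            -((years - p["peak_year"]) / p["peak_width"]) ** 2)
        dep = base * _lognoise(rng, sigma, years.size)
    elif name == "asia_grassland":
        # non-negative noisy increments after rise_start => monotone by construction
        base = np.full(years.size, p["start_level"])
        after = years >= p["rise_start"]
        inc = (p["rise_rate"] + p["rise_accel"] * (years[after] - p["rise_start"]))
        inc = inc * _lognoise(rng, sigma, inc.size)
        base[after] += np.cumsum(inc)
        dep = base
    else:  # pragma: no cover - guarded in NdepProfile
        raise ConfigurationError(name)
    return np.maximum(dep, 0.0)


# ---------------------------------------------------------------------------
# main generator


def generate_forcing(site_spec, years: tuple[int, int], profile: NdepProfile,
                     seed: int, template: ClimateTemplate | None = None) -> ForcingSeries:
    """Generate a complete seeded :class:`ForcingSeries` for one site.

    Parameters
    ----------
    site_spec
        Anything with ``site_id`` and ``biome_label`` attributes (the biome
        selects a climate template unless ``template`` is given).
    years
        Inclusive ``(first, last)`` range within 1851–2009.
    profile
        N-deposition trajectory shape.
    seed
        Master seed; identical inputs give bit-identical output.
    """
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise InputError("empty year range")
    if y0 < YEAR_MIN or y1 > YEAR_MAX:
        raise InputError(f"years must lie within [{YEAR_MIN}, {YEAR_MAX}]")
    if profile.profile_name not in PROFILE_NAMES:
        raise ConfigurationError(f"unknown deposition profile {profile.profile_name!r}")

    site_id = site_spec.site_id
    tmpl = template or CLIMATE_TEMPLATES[getattr(site_spec, "biome_label",
                                                 "temperate forest")]
    yrs = np.arange(y0, y1 + 1)
    n = yrs.size
    months = np.arange(1, 13)
    season = -np.cos(2 * np.pi * (months - 1) / 12.0)  # coldest in January

    # temperature: seasonal cycle + AR(1) annual anomaly + post-1970 trend
    rng_t = _rng(seed, site_id, "temperature")
    anom = np.empty(n)
    prev = 0.0
    innov = rng_t.normal(0.0, tmpl.t_anom_sigma, n)
    for i in range(n):
        prev = tmpl.t_ar1 * prev + innov[i]
        anom[i] = prev
    trend = tmpl.t_trend * np.maximum(yrs - tmpl.trend_start, 0)
    temp = (tmpl.t_mean + trend[:, None] + anom[:, None]
            + tmpl.t_amp * season[None, :]
            + rng_t.normal(0.0, tmpl.t_month_sigma, (n, 12)))

    # precipitation: seasonal shape × mean-one lognormal noise
    rng_p = _rng(seed, site_id, "precipitation")
    p_month = (tmpl.p_annual / 12.0) * (1.0 + tmpl.p_season_amp * season)
    precip = p_month[None, :] * _lognoise(rng_p, tmpl.p_noise_sigma, (n, 12))

    rng_c = _rng(seed, site_id, "cloud")
    cloud = np.clip(rng_c.normal(tmpl.cloud_mean, tmpl.cloud_sigma, (n, 12)), 0.0, 1.0)
    rng_w = _rng(seed, site_id, "wind")
    wind = np.maximum(rng_w.normal(tmpl.wind_mean, tmpl.wind_sigma, (n, 12)), 0.0)
    rng_wd = _rng(seed, site_id, "wet_days")
    wetd = np.clip(rng_wd.normal(tmpl.wetdays_mean, tmpl.wetdays_sigma, (n, 12)),
                   0.0, 31.0)
    rng_rh = _rng(seed, site_id, "relative_humidity")
    rh = np.clip(rng_rh.normal(tmpl.rh_mean, tmpl.rh_sigma, (n, 12)), 0.0, 100.0)

    dep = generate_ndep(profile, yrs, _rng(seed, site_id, "n_deposition"))

    out = ForcingSeries(site_id, yrs, temp, precip, cloud, wind, wetd, rh,
                        co2_trajectory(yrs), dep)
    out.validate()
    return out


def spinup_climatology(forcing: ForcingSeries,
                       window: tuple[int, int] | None = None) -> ForcingSeries:
    """Repeating-year climatology of a forcing series.

    Each calendar month of every output year equals the multi-year mean of that
    month over ``window`` (default: all input years). CO₂ is held at the
    series' first-year value. N deposition is copied unchanged — the
    experiment protocol overrides it explicitly.
    """
    if forcing.years.size < 10:
        raise InputError("climatology needs at least 10 years of forcing")
    if window is None:
        sel = slice(None)
    else:
        i0 = forcing.year_index(window[0])
        i1 = forcing.year_index(window[1])
        sel = slice(i0, i1 + 1)
    out = forcing.copy()
    for name in ("monthly_temperature", "monthly_precipitation", "cloud_fraction",
                 "wind_speed", "wet_days", "relative_humidity"):
        arr = getattr(forcing, name)
        mean = arr[sel].mean(axis=0)
        setattr(out, name, np.tile(mean, (forcing.years.size, 1)))
    out.co2 = np.full_like(forcing.co2, forcing.co2[0])
    return out


_DRIVER_FIELDS = {
    "temperature": ("monthly_temperature",),
    "precipitation": ("monthly_precipitation",),
    "co2": ("co2",),
    "n_deposition": ("n_deposition",),
}


def freeze_driver(forcing: ForcingSeries, driver: str, freeze_year: int) -> ForcingSeries:
    """Hold one driver at its ``freeze_year`` values for all later years.

    All other drivers are untouched; freezing twice is idempotent.
    """
    if driver not in _DRIVER_FIELDS:
        raise InputError(f"unknown driver {driver!r}; expected one of "
                         f"{sorted(_DRIVER_FIELDS)}")
    idx = forcing.year_index(freeze_year)
    out = forcing.copy()
    for name in _DRIVER_FIELDS[driver]:
        arr = getattr(out, name)
        arr[idx + 1:] = arr[idx]
    return out


# ---------------------------------------------------------------------------
# multi-site tidy CSV I/O


def forcing_to_frames(series: Iterable[ForcingSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    climates, annuals = [], []
    for s in series:
        c, a = s.to_frames()
        climates.append(c)
        annuals.append(a)
    return pd.concat(climates, ignore_index=True), pd.concat(annuals, ignore_index=True)


def frames_to_forcing(climate: pd.DataFrame,
                      annual: pd.DataFrame) -> dict[str, ForcingSeries]:
    return {sid: ForcingSeries.from_frames(climate, annual, sid)
            for sid in annual["site_id"].unique()}
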