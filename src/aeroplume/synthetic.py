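"""Synthetic flight-activity and station scenarios.

Real monthly turnover statistics behind airport emission inventories are
published as web tables that are not archived in machine-readable form, so
this module generates inputs with the same statistical structure, letting
every pipeline stage — and end-to-end parameter recovery — be tested
without downloads.

The national monthly turnover follows

    national(y, m) = base * (1 + growth)^(y - y0) * seasonal(m) * shock(y)

with mean-one seasonal multipliers peaking in August and troughing in
February, a compound annual growth trend, and an optional pandemic-style
shock year whose annual total drops by ``shock_depth`` relative to the
undisturbed trend, followed by a partial multiplicative recovery.  Airport
shares come from a Dirichlet draw whose concentration parameter is set so
a handful of hub airports dominate, mirroring real networks.  Turnover
noise is multiplicative log-normal (keeps positivity); station noise is
additive truncated normal on top of the modeled concentration plus a
background offset standing in for non-aviation sources near the airport.

The default seasonal shape places the seasonality on the daily traffic
rate and then scales by month length, so both monthly emission mass and
emission flow peak in August and trough in February (a purely monthly
multiplier cannot do this: January's 31 days would undercut February's 28
at the flow level).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .emissions import AirportRecord
from .validation import CAN_STATION_DISTANCES_KM, CAN_STATION_IDS, StationObservation

__all__ = [
    "ScenarioConfig",
    "DEFAULT_SEASONAL_AMPLITUDE",
    "default_seasonal_multipliers",
    "full_network_config",
    "shock_factor",
    "national_turnover",
    "generate_airports",
    "generate_shares",
    "generate_activity",
    "generate_fuel_params",
    "generate_station_observations",
]

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: Default daily-rate seasonal amplitude; derived from a reported August/February
#: monthly emission ratio of ~1.195 after removing the 31/28 day-count factor.
DEFAULT_SEASONAL_AMPLITUDE = 0.0381

# Internal RNG stream tags so airports, activity and stations draw
# independently from one scenario seed.
_STREAM_AIRPORTS = 1
_STREAM_SHARES = 2
_STREAM_ACTIVITY = 3
_STREAM_STATIONS = 4


def default_seasonal_multipliers(
    amplitude: float = DEFAULT_SEASONAL_AMPLITUDE,
) -> tuple[float, ...]:
    """Mean-one monthly multipliers: cosine daily rate (Aug peak, Feb trough)
    scaled by month length, then normalised."""
    months = np.arange(1, 13)
    daily_rate = 1.0 + amplitude * np.cos(2.0 * np.pi * (months - 8) / 12.0)
    m = _MONTH_DAYS * daily_rate
    m = m / m.mean()
    return tuple(float(x) for x in m)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one synthetic study scenario.

    Defaults describe a compact three-year scenario around a shock year:
    20 airports, double-digit trend growth, a 31.65% shock-year contraction
    relative to trend and a 4.77% partial recovery the following year —
    the magnitudes reported for the Chinese aviation network around 2020.
    """

    n_airports: int = 20
    years: tuple[int, int] = (2019, 2021)  # inclusive
    base_national_turnover: float = 5.0e8  # ton-km per average month in years[0]
    annual_growth: float = 0.10
    seasonal_multipliers: tuple[float, ...] = field(
        default_factory=default_seasonal_multipliers
    )
    shock_year: int | None = 2020
    shock_depth: float = 0.3165
    recovery_rate: float = 0.0477
    coastal_fraction: float = 0.4
    airport_share_concentration: float = 0.5
    noise_sd: float = 0.05  # relative, log-normal on turnover
    unit_fuel_consumption: float = 0.30  # kg fuel per ton-km
    emission_intensity: float = 0.2772  # g PM2.5 per kg fuel
    station_background_frac: float = 0.06  # non-aviation background, fraction of signal
    station_noise_sd: float = 0.0  # absolute, ug/m^3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_airports < 1:
            raise ValueError(f"n_airports must be >= 1, got {self.n_airports}")
        if self.years[0] > self.years[1]:
            raise ValueError(f"years range is empty: {self.years}")
        m = np.asarray(self.seasonal_multipliers, dtype=float)
        if m.shape != (12,):
            raise ValueError("seasonal_multipliers must have 12 entries")
        if np.any(m <= 0):
            raise ValueError("seasonal multipliers must be positive")
        if abs(m.mean() - 1.0) > 1e-9:
            raise ValueError(f"seasonal multipliers must average 1, got mean {m.mean()}")
        if not 0.0 <= self.shock_depth < 1.0:
            raise ValueError(f"shock_depth must be in [0, 1), got {self.shock_depth}")
        if not 0.0 <= self.coastal_fraction <= 1.0:
            raise ValueError(f"coastal_fraction must be in [0, 1], got {self.coastal_fraction}")
        if not self.airport_share_concentration > 0:
            raise ValueError("airport_share_concentration must be positive")
        if self.noise_sd < 0 or self.station_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


def full_network_config(seed: int = 0) -> ScenarioConfig:
    """Full-network preset: 175 airports over 2006-2023 with a 2020 shock."""
    return ScenarioConfig(
        n_airports=175,
        years=(2006, 2023),
        base_national_turnover=2.5e9,
        shock_year=2020,
        seed=seed,
    )


def shock_factor(config: ScenarioConfig, year: int) -> float:
    """Multiplier on the undisturbed trend: 1 before the shock, 1 - depth in
    the shock year, partial compound recovery (capped at 1) afterwards."""
    if config.shock_year is None or year < config.shock_year:
        return 1.0
    factor = (1.0 - config.shock_depth) * (1.0 + config.recovery_rate) ** (
        year - config.shock_year
    )
    return min(1.0, factor)


def national_turnover(config: ScenarioConfig, year: int, month: int) -> float:
    """Noise-free national turnover (ton-km) for one month."""
    y0 = config.years[0]
    trend = config.base_national_turnover * (1.0 + config.annual_growth) ** (year - y0)
    return trend * config.seasonal_multipliers[month - 1] * shock_factor(config, year)


def _make_codes(n: int, rng: np.random.Generator) -> list[str]:
    letters = np.array(list(string.ascii_uppercase))
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < n:
        code = "".join(rng.choice(letters, size=3))
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


def generate_airports(config: ScenarioConfig) -> list[AirportRecord]:
    """Deterministic synthetic registry: unique 3-letter codes, coastal flags."""
    if config.n_airports < 1:
        raise ValueError(f"n_airports must be >= 1, got {config.n_airports}")
    rng = np.random.default_rng([config.seed, _STREAM_AIRPORTS])
    codes = _make_codes(config.n_airports, rng)
    coastal = rng.random(config.n_airports) < config.coastal_fraction
    return [AirportRecord(code=c, coastal=bool(f)) for c, f in zip(codes, coastal)]


def generate_shares(config: ScenarioConfig) -> np.ndarray:
    """Dirichlet airport shares; a small concentration parameter makes a few
    hub airports dominate."""
    rng = np.random.default_rng([config.seed, _STREAM_SHARES])
    alpha = np.full(config.n_airports, config.airport_share_concentration)
    return rng.dirichlet(alpha)


def generate_activity(
    config: ScenarioConfig, airports: Sequence[AirportRecord]
) -> pd.DataFrame:
    """Per-airport-month turnover table (columns ``year, month, airport,
    turnover_tonkm``), reproducible for a fixed seed."""
    shares = generate_shares(config)
    if len(shares) != len(airports):
        raise ValueError("airport list does not match configured n_airports")
    rng = np.random.default_rng([config.seed, _STREAM_ACTIVITY])
    rows = []
    for year in config.year_range():
        for month in range(1, 13):
            national = national_turnover(config, year, month)
            for airport, share in zip(airports, shares):
                rows.append((year, month, airport.code, national * share))
    df = pd.DataFrame(rows, columns=["year", "month", "airport", "turnover_tonkm"])
    if config.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(df)))
        df["turnover_tonkm"] = df["turnover_tonkm"] * noise
    return df


def generate_fuel_params(config: ScenarioConfig) -> pd.DataFrame:
    """Unit ton-km consumption table; constant by default."""
    rows = [
        (year, month, config.unit_fuel_consumption)
        for year in config.year_range()
        for month in range(1, 13)
    ]
    return pd.DataFrame(
        rows, columns=["year", "month", "unit_consumption_kg_per_tonkm"]
    )


def generate_station_observations(
    true_concentration: float,
    distances_km: Sequence[float] = CAN_STATION_DISTANCES_KM,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    station_ids: Sequence[str] | None = None,
) -> list[StationObservation]:
    """Stations observing ``true + background + noise`` (truncated at zero).

    ``background`` stands in for non-aviation PM2.5 sources near the
    airport; noise is additive normal with standard deviation ``noise_sd``.
    """
    d = np.asarray(distances_km, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    if station_ids is None:
        if len(d) == len(CAN_STATION_DISTANCES_KM) and tuple(d) == CAN_STATION_DISTANCES_KM:
            station_ids = CAN_STATION_IDS
        else:
            station_ids = [f"S{i:03d}" for i in range(len(d))]
    rng = np.random.default_rng([seed, _STREAM_STATIONS])
    eps = rng.normal(0.0, noise_sd, size=len(d)) if noise_sd > 0 else np.zeros(len(d))
    observed = np.maximum(true_concentration + background + eps, 0.0)
    return [
        StationObservation(station_id=sid, distance_km=float(dist), observed=float(obs))
        for sid, dist, obs in zip(station_ids, d, observed)
    ]
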