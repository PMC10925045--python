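"""Aircraft LTO-stage PM2.5 emission accounting.

The emission chain is purely multiplicative: national monthly air-transport
turnover (ton-km) is apportioned to airports by their turnover share, fuel
burn follows from the unit ton-kilometre consumption (kg fuel per ton-km),
PM2.5 mass from a fleet-average emission intensity (g PM2.5 per kg fuel),
and the monthly mass is averaged over the month's seconds to an emission
flow ``E`` in g/s — the source strength consumed by the dispersion model.

The emission intensity abstracts a full per-engine emission-index method
behind a pluggable interface: any callable ``(airport, year, month) -> g/kg``
is accepted, with constant and per-year implementations provided. The
default constant, 0.2772 g/kg, is a published national fleet-average LTO
intensity for a recent, predominantly narrow-body Chinese fleet.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AirportRecord",
    "ConstantIntensity",
    "PerYearIntensity",
    "DEFAULT_EMISSION_INTENSITY_G_PER_KG",
    "SECONDS_PER_DAY",
    "days_in_month",
    "seconds_in_month",
    "compute_turnover_shares",
    "compute_fuel",
    "compute_emission_mass",
    "mass_to_flow",
    "build_emission_table",
]

#: Fleet-average LTO PM2.5 emission intensity, g per kg fuel (2018 national value).
DEFAULT_EMISSION_INTENSITY_G_PER_KG = 0.2772

SECONDS_PER_DAY = 86_400

_CODE_RE = re.compile(r"^[A-Z]{3}$")

#: Columns of the long-format emission table.
EMISSION_COLUMNS = ("year", "month", "airport", "fuel_kg", "pm25_g", "flow_g_per_s")


@dataclass(frozen=True)
class AirportRecord:
    """An airport's identity and the attributes the dispersion step needs.

    Parameters
    ----------
    code
        Three-letter IATA identifier, e.g. ``"CAN"``.
    coastal
        Whether the airport sits in the coastal mixing regime (lower
        boundary-layer lid, 900 m) rather than the inland one (1100 m).
    mixing_layer_override
        Explicit mixing-layer height in metres; when given it takes
        precedence over the coastal/inland default.
    """

    code: str
    coastal: bool
    mixing_layer_override: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.code, str) or not _CODE_RE.match(self.code):
            raise ValueError(
                f"airport code must be three uppercase letters, got {self.code!r}"
            )
        if self.mixing_layer_override is not None and not self.mixing_layer_override > 0:
            raise ValueError(
                f"mixing_layer_override must be positive, got {self.mixing_layer_override}"
            )


class ConstantIntensity:
    """Emission intensity fixed at a single g-per-kg value for all months."""

    def __init__(self, g_per_kg: float = DEFAULT_EMISSION_INTENSITY_G_PER_KG):
        if not g_per_kg > 0:
            raise ValueError(f"emission intensity must be positive, got {g_per_kg}")
        self.g_per_kg = float(g_per_kg)

    def __call__(self, airport: str, year: int, month: int) -> float:
        return self.g_per_kg

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ConstantIntensity({self.g_per_kg})"


class PerYearIntensity:
    """Emission intensity varying by calendar year (fleet-mix drift)."""

    def __init__(self, by_year: Mapping[int, float], default: float | None = None):
        for year, value in by_year.items():
            if not value > 0:
                raise ValueError(f"intensity for {year} must be positive, got {value}")
        if default is not None and not default > 0:
            raise ValueError(f"default intensity must be positive, got {default}")
        self.by_year = dict(by_year)
        self.default = default

    def __call__(self, airport: str, year: int, month: int) -> float:
        try:
            return self.by_year[year]
        except KeyError:
            if self.default is None:
                raise KeyError(f"no emission intensity configured for year {year}")
            return self.default


IntensityModel = Callable[[str, int, int], float]


def days_in_month(year: int, month: int) -> int:
    """Gregorian day count of a month, leap-year aware."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return calendar.monthrange(year, month)[1]


def seconds_in_month(year: int, month: int) -> int:
    return days_in_month(year, month) * SECONDS_PER_DAY


def compute_turnover_shares(turnover: Mapping[str, float]) -> dict[str, float]:
    """Apportionment shares for one month: each airport's fraction of total.

    Raises
    ------
    ValueError
        If any turnover is negative, or if every airport reports zero
        activity (nothing to apportion).
    """
    if not turnover:
        raise ValueError("no airports supplied")
    for code, value in turnover.items():
        if value < 0:
            raise ValueError(f"turnover must be non-negative, got {value} for {code!r}")
    total = float(sum(turnover.values()))
    if total == 0.0:
        raise ValueError("all turnovers are zero: no activity to apportion")
    return {code: value / total for code, value in turnover.items()}


def compute_fuel(turnover_tonkm: float, unit_consumption_kg_per_tonkm: float) -> float:
    """Fuel burn in kg from transport output and unit ton-km consumption."""
    if np.any(np.asarray(turnover_tonkm) < 0):
        raise ValueError(f"turnover must be non-negative, got {turnover_tonkm}")
    if np.any(np.asarray(unit_consumption_kg_per_tonkm) < 0):
        raise ValueError(
            f"unit consumption must be non-negative, got {unit_consumption_kg_per_tonkm}"
        )
    return turnover_tonkm * unit_consumption_kg_per_tonkm


def compute_emission_mass(fuel_kg: float, intensity_g_per_kg: float) -> float:
    """PM2.5 mass in grams from fuel burn and emission intensity."""
    if np.any(np.asarray(fuel_kg) < 0):
        raise ValueError(f"fuel must be non-negative, got {fuel_kg}")
    if np.any(np.asarray(intensity_g_per_kg) <= 0):
        raise ValueError(f"emission intensity must be positive, got {intensity_g_per_kg}")
    return fuel_kg * intensity_g_per_kg


def mass_to_flow(mass_g: float, year: int, month: int) -> float:
    """Average a monthly PM2.5 mass (g) over the month's seconds to a flow in g/s."""
    if np.any(np.asarray(mass_g) < 0):
        raise ValueError(f"mass must be non-negative, got {mass_g}")
    return mass_g / seconds_in_month(year, month)


def _resolve_intensity(intensity) -> IntensityModel:
    if callable(intensity):
        return intensity
    if isinstance(intensity, Mapping):
        return PerYearIntensity(intensity)
    return ConstantIntensity(float(intensity))


def build_emission_table(
    activity: pd.DataFrame,
    fuel_params: pd.DataFrame,
    intensity=DEFAULT_EMISSION_INTENSITY_G_PER_KG,
    share_basis: str = "turnover",
) -> pd.DataFrame:
    """Compute the full per-airport-month emission table.

    Parameters
    ----------
    activity
        Long table with columns ``year, month, airport, turnover_tonkm``
        (and ``lto_count`` when ``share_basis="lto_count"``); one row per
        airport-month. Zero-turnover airports are kept and receive zero
        emissions so output tables stay rectangular.
    fuel_params
        Table with columns ``year, month, unit_consumption_kg_per_tonkm``.
    intensity
        A g-per-kg scalar, a ``{year: g_per_kg}`` mapping, or any callable
        ``(airport, year, month) -> g_per_kg``.
    share_basis
        ``"turnover"`` uses each airport's own ton-km directly. With
        ``"lto_count"`` the month's total turnover is re-apportioned by
        landing/take-off counts before fuel is computed.

    Returns
    -------
    DataFrame with columns ``year, month, airport, fuel_kg, pm25_g,
    flow_g_per_s``.
    """
    required = {"year", "month", "airport", "turnover_tonkm"}
    missing = required - set(activity.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if activity.duplicated(["year", "month", "airport"]).any():
        dupes = activity[activity.duplicated(["year", "month", "airport"])]
        raise ValueError(
            f"duplicate (year, month, airport) rows in activity: {dupes.iloc[0].tolist()}"
        )
    if (activity["turnover_tonkm"] < 0).any():
        raise ValueError("activity contains negative turnover")

    df = activity.copy()
    if share_basis == "lto_count":
        if "lto_count" not in df.columns:
            raise ValueError('share_basis="lto_count" requires an lto_count column')
        grp = df.groupby(["year", "month"])
        month_total = grp["turnover_tonkm"].transform("sum")
        lto_total = grp["lto_count"].transform("sum")
        if (lto_total == 0).any():
            raise ValueError("a month has zero total LTO count: nothing to apportion")
        df["turnover_tonkm"] = month_total * df["lto_count"] / lto_total
    elif share_basis != "turnover":
        raise ValueError(f"unknown share basis {share_basis!r}")

    fp = fuel_params[["year", "month", "unit_consumption_kg_per_tonkm"]]
    if (fp["unit_consumption_kg_per_tonkm"] <= 0).any():
        raise ValueError("unit consumption must be positive")
    merged = df.merge(fp, on=["year", "month"], how="left", validate="many_to_one")
    if merged["unit_consumption_kg_per_tonkm"].isna().any():
        bad = merged[merged["unit_consumption_kg_per_tonkm"].isna()]
        ym = (int(bad.iloc[0]["year"]), int(bad.iloc[0]["month"]))
        raise ValueError(f"no unit consumption configured for {ym}")

    model = _resolve_intensity(intensity)
    merged["fuel_kg"] = merged["turnover_tonkm"] * merged["unit_consumption_kg_per_tonkm"]
    merged["pm25_g"] = [
        compute_emission_mass(f, model(a, int(y), int(m)))
        for f, a, y, m in zip(
            merged["fuel_kg"], merged["airport"], merged["year"], merged["month"]
        )
    ]
    merged["flow_g_per_s"] = [
        mass_to_flow(g, int(y), int(m))
        for g, y, m in zip(merged["pm25_g"], merged["year"], merged["month"])
    ]
    return merged[list(EMISSION_COLUMNS)].reset_index(drop=True)
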