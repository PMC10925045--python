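"""Wide-table input/output and the end-to-end pipeline.

The distribution layout for both result tables (emission flow in g/s and
concentration in ug/m^3) is one row per (year, airport) with 14 columns:
Year, Airport, then Jan..Dec.  CSV is the primary on-disk dialect (UTF-8,
'.' decimal, values round-trip bit-exactly); XLSX writing mirrors the
spreadsheet medium the tables are usually distributed in.  Missing months
are empty cells, never 0 — zero is a meaningful emission value.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersion import PlumeParams, run_concentration_table
from .emissions import AirportRecord, build_emission_table
from .synthetic import (
    ScenarioConfig,
    generate_activity,
    generate_airports,
    generate_fuel_params,
    generate_station_observations,
)
from .validation import ValidationReport, validate_against_stations

__all__ = [
    "MONTH_NAMES",
    "WIDE_COLUMNS",
    "to_wide",
    "write_wide",
    "read_wide",
    "read_airports_csv",
    "write_airports_csv",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger("aeroplume")

MONTH_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)
WIDE_COLUMNS = ("Year", "Airport", *MONTH_NAMES)

#: Long-table value column per declared quantity kind.
KIND_VALUE_COLUMNS = {
    "flow": "flow_g_per_s",
    "concentration": "concentration_ugm3",
}

_CODE_RE = re.compile(r"^[A-Z]{3}$")


def to_wide(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Pivot a long (year, month, airport, value) table to the 14-column layout."""
    required = {"year", "month", "airport", value_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    dup = records.duplicated(["year", "airport", "month"])
    if dup.any():
        first = records[dup].iloc[0]
        raise ValueError(
            f"duplicate (year, airport, month): "
            f"({int(first['year'])}, {first['airport']!r}, {int(first['month'])})"
        )
    wide = records.pivot(index=["year", "airport"], columns="month", values=value_col)
    wide = wide.reindex(columns=range(1, 13))
    wide.columns = list(MONTH_NAMES)
    wide = wide.reset_index().rename(columns={"year": "Year", "airport": "Airport"})
    wide = wide.sort_values(["Year", "Airport"]).reset_index(drop=True)
    return wide[list(WIDE_COLUMNS)]


def write_wide(
    records: pd.DataFrame,
    kind: str,
    path: str | Path,
    dialect: str = "csv",
) -> Path:
    """Write a long result table in the wide Year/Airport/Jan..Dec layout.

    ``kind`` is ``"flow"`` or ``"concentration"`` and selects the value
    column of ``records``.
    """
    if kind not in KIND_VALUE_COLUMNS:
        raise ValueError(f"kind must be one of {sorted(KIND_VALUE_COLUMNS)}, got {kind!r}")
    wide = to_wide(records, KIND_VALUE_COLUMNS[kind])
    path = Path(path)
    if dialect == "csv":
        wide.to_csv(path, index=False)
    elif dialect == "xlsx":
        wide.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _parse_wide_row(
    lineno: int, row: Sequence[str]
) -> tuple[int, str, list[float]]:
    if len(row) != len(WIDE_COLUMNS):
        raise ValueError(
            f"line {lineno}: expected {len(WIDE_COLUMNS)} columns, got {len(row)}"
        )
    try:
        year = int(row[0])
    except ValueError:
        raise ValueError(f"line {lineno}: year {row[0]!r} is not an integer") from None
    if not 1000 <= year <= 9999:
        raise ValueError(f"line {lineno}: year {year} is not a 4-digit year")
    code = row[1]
    if not _CODE_RE.match(code):
        raise ValueError(f"line {lineno}: bad airport code {code!r}")
    values: list[float] = []
    for name, cell in zip(MONTH_NAMES, row[2:]):
        if cell == "":
            values.append(math.nan)
            continue
        try:
            values.append(float(cell))
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-numeric {name} cell {cell!r} for {code}"
            ) from None
    return year, code, values


def read_wide(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    """Read a wide table back into long form (inverse of :func:`write_wide`).

    Returns a long DataFrame ``year, month, airport, value`` with NaN for
    empty cells.  Malformed rows are reported with their line number.
    """
    path = Path(path)
    rows: list[tuple[int, str, list[float]]] = []
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ValueError(f"{path}: empty file") from None
            if tuple(header) != WIDE_COLUMNS:
                raise ValueError(f"{path}: unexpected header {header}")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                rows.append(_parse_wide_row(lineno, row))
    elif dialect == "xlsx":
        raw = pd.read_excel(path, engine="openpyxl", dtype=object)
        if tuple(raw.columns) != WIDE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {list(raw.columns)}")
        for i, rec in enumerate(raw.itertuples(index=False), start=2):
            cells = ["" if (c is None or (isinstance(c, float) and math.isnan(c))) else str(c)
                     for c in rec]
            rows.append(_parse_wide_row(i, cells))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: set[tuple[int, str]] = set()
    long_rows = []
    for year, code, values in rows:
        if (year, code) in seen:
            raise ValueError(f"duplicate (year, airport): ({year}, {code!r})")
        seen.add((year, code))
        for month, value in enumerate(values, start=1):
            long_rows.append((year, month, code, value))
    return pd.DataFrame(long_rows, columns=["year", "month", "airport", "value"])


def read_airports_csv(path: str | Path) -> list[AirportRecord]:
    """Registry CSV ``airport,coastal[,mixing_layer_override]`` with coastal in {0,1}."""
    df = pd.read_csv(path)
    if not {"airport", "coastal"} <= set(df.columns):
        raise ValueError(f"{path}: need columns airport,coastal")
    records = []
    for rec in df.itertuples(index=False):
        override = getattr(rec, "mixing_layer_override", None)
        if override is not None and (isinstance(override, float) and math.isnan(override)):
            override = None
        records.append(
            AirportRecord(
                code=str(rec.airport),
                coastal=bool(int(rec.coastal)),
                mixing_layer_override=override,
            )
        )
    return records


def write_airports_csv(airports: Sequence[AirportRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "airport": [a.code for a in airports],
            "coastal": [int(a.coastal) for a in airports],
            "mixing_layer_override": [a.mixing_layer_override for a in airports],
        }
    )
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    airports: list[AirportRecord]
    activity: pd.DataFrame
    emissions: pd.DataFrame  # long: year, month, airport, fuel_kg, pm25_g, flow_g_per_s
    concentrations: pd.DataFrame  # long: year, month, airport, concentration_ugm3
    validation: ValidationReport
    params: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: ScenarioConfig | None = None,
    plume: PlumeParams | None = None,
    out_dir: str | Path | None = None,
    idw_power: float = 1.0,
    radius_km: float = 50.0,
) -> PipelineResult:
    """Synthetic scenario -> emissions -> concentrations -> station validation.

    The validation stage picks the airport with the largest total turnover
    and the June of the scenario's middle year, synthesises station
    observations around its modeled concentration, and scores the model by
    IDW relative error.  Deterministic for a fixed config seed.

    When ``out_dir`` is given, both wide tables (CSV), the long emission
    table, the validation report and a parameter log are written there.
    """
    config = config if config is not None else ScenarioConfig()
    plume = plume if plume is not None else PlumeParams()

    params_log = {
        "scenario": dataclasses.asdict(config),
        "plume": dataclasses.asdict(plume),
        "idw_power": idw_power,
        "radius_km": radius_km,
    }
    logger.info("pipeline parameters: %s", params_log)

    airports = _stage("generate_airports")(generate_airports, config)
    activity = _stage("generate_activity")(generate_activity, config, airports)
    fuel_params = _stage("generate_fuel_params")(generate_fuel_params, config)
    emissions = _stage("emissions")(
        build_emission_table, activity, fuel_params, config.emission_intensity
    )
    concentrations = _stage("dispersion")(
        run_concentration_table, emissions, airports, plume
    )

    def _validate() -> ValidationReport:
        totals = activity.groupby("airport")["turnover_tonkm"].sum()
        top_airport = totals.idxmax()
        mid_year = (config.years[0] + config.years[1]) // 2
        month = 6
        sel = concentrations[
            (concentrations["airport"] == top_airport)
            & (concentrations["year"] == mid_year)
            & (concentrations["month"] == month)
        ]
        true_c = float(sel["concentration_ugm3"].iloc[0])
        stations = generate_station_observations(
            true_c,
            background=config.station_background_frac * true_c,
            noise_sd=config.station_noise_sd,
            seed=config.seed,
        )
        return validate_against_stations(
            true_c, stations, power=idw_power, radius_km=radius_km
        )

    report = _stage("validation")(_validate)

    result = PipelineResult(
        airports=airports,
        activity=activity,
        emissions=emissions,
        concentrations=concentrations,
        validation=report,
        params=params_log,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_airports_csv(airports, out_dir / "airports.csv")
        activity.to_csv(out_dir / "activity.csv", index=False)
        emissions.to_csv(out_dir / "emissions_long.csv", index=False)
        write_wide(emissions, "flow", out_dir / "monthly_pm25_flow.csv")
        write_wide(
            concentrations, "concentration", out_dir / "monthly_pm25_concentration.csv"
        )
        with open(out_dir / "validation.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(params_log, fh, indent=2, default=str)
        logger.info("pipeline outputs written to %s", out_dir)

    return result
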