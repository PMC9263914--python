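"""CSV input/output for the study's tabular formats.

All files are plain long-format CSV.  Water samples use the header
``sample_id,kind,date,treatment,depth_cm,d18O_permil,dD_permil,amount_mm``
with empty fields meaning "absent" and ISO-8601 dates.  Root-length data use
``date,treatment,plot,bin_top_cm,root_length_cm``; daily weather uses
``date,Rn,G,Tmean,u2,RHmean[,es,ea]``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .et0 import DEFAULT_ALTITUDE_M, WeatherDay, saturation_vapour_pressure
from .isotopes import SampleKind, WaterSample
from .rld import RLDProfile, normalize_rld

WATER_COLUMNS = [
    "sample_id", "kind", "date", "treatment",
    "depth_cm", "d18O_permil", "dD_permil", "amount_mm",
]
RLD_COLUMNS = ["date", "treatment", "plot", "bin_top_cm", "root_length_cm"]
WEATHER_COLUMNS = ["date", "Rn", "G", "Tmean", "u2", "RHmean"]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_water_samples(path) -> list[WaterSample]:
    df = pd.read_csv(path, dtype={"sample_id": str, "treatment": str}, float_precision="round_trip")
    _require(df, WATER_COLUMNS, path)
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            WaterSample(
                sample_id=str(row.sample_id),
                kind=SampleKind(row.kind),
                date=_dt.date.fromisoformat(str(row.date)),
                treatment="" if pd.isna(row.treatment) else str(row.treatment),
                depth_cm=None if pd.isna(row.depth_cm) else float(row.depth_cm),
                d18O_permil=float(row.d18O_permil),
                dD_permil=float(row.dD_permil),
                amount_mm=None if pd.isna(row.amount_mm) else float(row.amount_mm),
            )
        )
    return samples


def write_water_samples(samples: Sequence[WaterSample], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "kind": [s.kind.value for s in samples],
            "date": [s.date.isoformat() for s in samples],
            "treatment": [s.treatment for s in samples],
            "depth_cm": [s.depth_cm for s in samples],
            "d18O_permil": [s.d18O_permil for s in samples],
            "dD_permil": [s.dD_permil for s in samples],
            "amount_mm": [s.amount_mm for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_rld_profiles(path) -> dict[tuple[str, str, str], RLDProfile]:
    """RLD profiles keyed by (date, treatment, plot)."""
    df = pd.read_csv(path, dtype={"treatment": str, "plot": str}, float_precision="round_trip")
    _require(df, RLD_COLUMNS, path)
    profiles = {}
    for key, grp in df.groupby(["date", "treatment", "plot"], sort=True):
        grp = grp.sort_values("bin_top_cm")
        profiles[tuple(str(k) for k in key)] = normalize_rld(
            grp["root_length_cm"].to_numpy(), grp["bin_top_cm"].to_numpy()
        )
    return profiles


def write_rld_profiles(rows: pd.DataFrame, path) -> None:
    _require(rows, RLD_COLUMNS, path)
    rows.to_csv(path, index=False)


def read_weather(path) -> list[WeatherDay]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, WEATHER_COLUMNS, path)
    days = []
    for row in df.itertuples(index=False):
        date = _dt.date.fromisoformat(str(row.date))
        if "es" in df.columns and not pd.isna(getattr(row, "es", np.nan)):
            days.append(
                WeatherDay(date, float(row.Rn), float(row.G), float(row.Tmean),
                           float(row.u2), es=float(row.es), ea=float(row.ea))
            )
        else:
            days.append(
                WeatherDay.from_relative_humidity(
                    date, float(row.Rn), float(row.G), float(row.Tmean),
                    float(row.u2), float(row.RHmean), DEFAULT_ALTITUDE_M,
                )
            )
    return days


def write_weather(days: Sequence[WeatherDay], path) -> None:
    df = pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in days],
            "Rn": [d.Rn for d in days],
            "G": [d.G for d in days],
            "Tmean": [d.T_mean for d in days],
            "u2": [d.u2 for d in days],
            "RHmean": [100.0 * d.ea / d.es for d in days],
            "es": [d.es for d in days],
            "ea": [d.ea for d in days],
        }
    )
    df.to_csv(path, index=False)
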