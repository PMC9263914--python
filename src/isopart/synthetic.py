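"""Seeded generator for a full study-shaped dataset with known ground truth.

The generator emulates the structure of a two-factor (planting pattern ×
nitrogen) maize field campaign: per sampling date and treatment it produces
a depth-declining soil δ¹⁸O profile with evaporative surface enrichment,
stem water formed as a convex mixture of the soil-layer sources plus
measurement noise, precipitation events scattered about a local meteoric
water line, approximately exponential-with-depth root-length-density
profiles, a saturating uptake-vs-RLD point cloud, and a daily weather
series.  Every ground-truth parameter is recorded so each pipeline stage can
be checked against what generated the data.

All randomness flows from a single seed through named substreams (soil,
stem, rld, precip, weather, fractions), so each stage is independently
reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .et0 import WeatherDay, saturation_vapour_pressure
from .io import write_water_samples, write_weather
from .isotopes import SampleKind, WaterSample
from .mixing import DEFAULT_LAYER_BOUNDS, build_sources
from .rld import RLDProfile, normalize_rld, saturating_model

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset"]

#: Soil sampling depths (cm) of the emulated campaign.
SOIL_SAMPLING_DEPTHS = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)

_SUBSTREAMS = ("soil", "stem", "rld", "precip", "weather", "fractions")


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults mirror the emulated campaign: six sampling dates by six
    treatments in one season, measurement noise of 0.1 ‰ (δ¹⁸O) and 1.4 ‰
    (δD) on stem water, the season's local meteoric water line, and the
    season's saturating uptake curve.
    """

    seed: int = 0
    n_dates: int = 6
    start_date: _dt.date = _dt.date(2016, 6, 24)
    date_step_days: int = 19
    treatments: tuple[str, ...] = (
        "P1-N120", "P1-N240", "P2-N120", "P2-N240", "P3-N120", "P3-N240",
    )
    layer_bounds: tuple[tuple[float, float], ...] = DEFAULT_LAYER_BOUNDS
    #: optional fixed truth per (date_iso, treatment); groups not listed get
    #: a Dirichlet draw from the ``fractions`` substream
    true_fractions: dict | None = None
    fraction_alpha: tuple[float, ...] = (2.0, 4.0, 2.0, 1.0)

    # soil profile: base linear decline + surface evaporative enrichment
    d18O_surface: float = -6.0
    profile_gradient_permil_per_cm: float = -0.05
    surface_enrichment_permil: float = 3.0
    enrichment_efold_cm: float = 7.0
    soil_jitter_sd_d18O: float = 0.3
    soil_jitter_sd_dD: float = 1.5
    #: soil water plots beneath the meteoric line on an evaporation line
    evap_slope: float = 5.5
    evap_intercept: float = -8.0
    #: deep soil water retains meteoric deuterium-excess that surface
    #: evaporation has stripped: δD recovers toward the meteoric line with
    #: depth by this amplitude (‰) over the given e-folding scale
    dexcess_depth_amplitude: float = 5.0
    dexcess_efold_cm: float = 30.0

    # stem water measurement noise
    stem_sd_d18O: float = 0.1
    stem_sd_dD: float = 1.4

    # meteoric line and precipitation events
    lmwl_slope: float = 6.7935
    lmwl_intercept: float = 2.0593
    n_rain_events: int = 15
    rain_event_range_mm: tuple[float, float] = (1.0, 60.0)
    precip_d18O_range: tuple[float, float] = (-9.4, -3.2)
    precip_scatter_sd_dD: float = 3.0

    # root-length density and the saturating uptake relation
    rld_decay_per_cm: float = 0.03
    rld_total_length_cm: float = 2000.0
    rld_jitter_cv: float = 0.10
    uptake_k: float = 234.24
    uptake_A: float = 207.72
    n_uptake_points: int = 60
    uptake_S_range: tuple[float, float] = (1.0, 1000.0)
    uptake_noise_frac_of_k: float = 0.05

    # daily weather
    n_weather_days: int = 100
    T_range: tuple[float, float] = (20.0, 32.0)
    Rn_range: tuple[float, float] = (10.0, 18.0)
    G_range: tuple[float, float] = (0.0, 1.0)
    u2_range: tuple[float, float] = (0.3, 3.0)
    RH_range: tuple[float, float] = (40.0, 90.0)

    def noiseless(self) -> "SyntheticConfig":
        """A copy with every noise source silenced (ground truth exact)."""
        return replace(
            self,
            soil_jitter_sd_d18O=0.0,
            soil_jitter_sd_dD=0.0,
            stem_sd_d18O=0.0,
            stem_sd_dD=0.0,
            precip_scatter_sd_dD=0.0,
            rld_jitter_cv=0.0,
            uptake_noise_frac_of_k=0.0,
        )

    # -- derived quantities ---------------------------------------------

    def dates(self) -> list[_dt.date]:
        return [
            self.start_date + _dt.timedelta(days=i * self.date_step_days)
            for i in range(self.n_dates)
        ]

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator derived from the master seed."""
        idx = _SUBSTREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[idx])

    def soil_d18O(self, depth_cm: float) -> float:
        """Noise-free soil δ¹⁸O at a depth (‰)."""
        base = self.d18O_surface + self.profile_gradient_permil_per_cm * depth_cm
        return base + self.surface_enrichment_permil * float(
            np.exp(-depth_cm / self.enrichment_efold_cm)
        )

    def soil_dD(self, d18O: float, depth_cm: float = 0.0) -> float:
        """Noise-free soil δD from δ¹⁸O via the evaporation-displaced line.

        The displacement beneath the meteoric line is strongest at the
        surface and relaxes with depth (depth-dependent deuterium excess),
        so δD carries depth information independent of δ¹⁸O.
        """
        base = self.evap_slope * d18O + self.evap_intercept
        return base + self.dexcess_depth_amplitude * (
            1.0 - float(np.exp(-depth_cm / self.dexcess_efold_cm))
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    water_samples: list[WaterSample]
    rld: pd.DataFrame
    uptake_points: list[tuple[float, float]]
    weather: list[WeatherDay]
    truth: dict


def _group_fractions(config: SyntheticConfig) -> dict[tuple[str, str], tuple[float, ...]]:
    """True uptake fractions per (date, treatment); fixed or Dirichlet-drawn."""
    n_layers = len(config.layer_bounds)
    alpha = np.asarray(config.fraction_alpha, dtype=float)
    if alpha.size != n_layers:
        alpha = np.ones(n_layers)
    rng = config.rng("fractions")
    out: dict[tuple[str, str], tuple[float, ...]] = {}
    for date in config.dates():
        for trt in config.treatments:
            key = (date.isoformat(), trt)
            if config.true_fractions and key in config.true_fractions:
                f = np.asarray(config.true_fractions[key], dtype=float)
                if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
                    raise ValueError(f"true_fractions for {key} not on the simplex")
            else:
                f = rng.dirichlet(alpha)
            out[key] = tuple(float(x) for x in f)
    return out


def generate_soil_profiles(config: SyntheticConfig) -> list[WaterSample]:
    """Soil samples at the campaign depths for every (date, treatment)."""
    rng = config.rng("soil")
    samples: list[WaterSample] = []
    for date in config.dates():
        for trt in config.treatments:
            for depth in SOIL_SAMPLING_DEPTHS:
                d18O = config.soil_d18O(depth) + rng.normal(0.0, config.soil_jitter_sd_d18O) \
                    if config.soil_jitter_sd_d18O > 0 else config.soil_d18O(depth)
                dD = config.soil_dD(d18O, depth)
                if config.soil_jitter_sd_dD > 0:
                    dD += rng.normal(0.0, config.soil_jitter_sd_dD)
                samples.append(
                    WaterSample(
                        sample_id=f"soil-{date.isoformat()}-{trt}-{depth:g}cm",
                        kind=SampleKind.SOIL,
                        date=date,
                        treatment=trt,
                        depth_cm=depth,
                        d18O_permil=d18O,
                        dD_permil=dD,
                    )
                )
    return samples


def generate_stem_samples(
    config: SyntheticConfig, soil_samples: Sequence[WaterSample]
) -> list[WaterSample]:
    """Stem water as the true-fraction mixture of layer means plus noise."""
    rng = config.rng("stem")
    fractions = _group_fractions(config)
    samples: list[WaterSample] = []
    for date in config.dates():
        for trt in config.treatments:
            group = [
                s for s in soil_samples if s.date == date and s.treatment == trt
            ]
            sources = build_sources(group, config.layer_bounds)
            f = np.asarray(fractions[(date.isoformat(), trt)])
            d18O = float(f @ [s.mean_d18O for s in sources])
            dD = float(f @ [s.mean_dD for s in sources])
            if config.stem_sd_d18O > 0:
                d18O += rng.normal(0.0, config.stem_sd_d18O)
            if config.stem_sd_dD > 0:
                dD += rng.normal(0.0, config.stem_sd_dD)
            samples.append(
                WaterSample(
                    sample_id=f"stem-{date.isoformat()}-{trt}",
                    kind=SampleKind.STEM,
                    date=date,
                    treatment=trt,
                    d18O_permil=d18O,
                    dD_permil=dD,
                )
            )
    return samples


def generate_rld_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Long-format RLD rows, bins declining ~exponentially with depth."""
    rng = config.rng("rld")
    bin_tops = np.arange(0.0, 100.0, 10.0)
    mids = bin_tops + 5.0
    rows = []
    for date in config.dates():
        for trt in config.treatments:
            weights = np.exp(-config.rld_decay_per_cm * mids)
            lengths = config.rld_total_length_cm * weights / weights.sum()
            if config.rld_jitter_cv > 0:
                lengths = lengths * rng.lognormal(
                    mean=0.0, sigma=config.rld_jitter_cv, size=lengths.size
                )
            for top, length in zip(bin_tops, lengths):
                rows.append(
                    {
                        "date": date.isoformat(),
                        "treatment": trt,
                        "plot": "1",
                        "bin_top_cm": float(top),
                        "root_length_cm": float(length),
                    }
                )
    return pd.DataFrame(rows)


def generate_uptake_points(config: SyntheticConfig) -> list[tuple[float, float]]:
    """(S, y) points on/about the true saturating uptake curve."""
    # dedicated child of the rld substream so RLD rows and uptake points
    # stay independently reproducible
    rld_ss = np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS))[_SUBSTREAMS.index("rld")]
    rng = np.random.default_rng(rld_ss.spawn(2)[1])
    lo, hi = config.uptake_S_range
    S = np.linspace(lo, hi, config.n_uptake_points)
    y = saturating_model(S, config.uptake_k, config.uptake_A)
    if config.uptake_noise_frac_of_k > 0:
        y = y + rng.normal(0.0, config.uptake_noise_frac_of_k * config.uptake_k, size=S.size)
    return [(float(s), float(v)) for s, v in zip(S, y)]


def generate_precipitation(config: SyntheticConfig) -> list[WaterSample]:
    """Rain events scattered about the configured local meteoric water line.

    Amounts span the configured range, deliberately including events of
    ≤ 5 mm so the downstream small-event filter is exercised.
    """
    rng = config.rng("precip")
    dates = config.dates()
    season_days = (dates[-1] - dates[0]).days or 1
    samples: list[WaterSample] = []
    for i in range(config.n_rain_events):
        offset = int(rng.integers(0, season_days + 1))
        date = dates[0] + _dt.timedelta(days=offset)
        amount = float(rng.uniform(*config.rain_event_range_mm))
        d18O = float(rng.uniform(*config.precip_d18O_range))
        dD = config.lmwl_slope * d18O + config.lmwl_intercept
        if config.precip_scatter_sd_dD > 0:
            dD += rng.normal(0.0, config.precip_scatter_sd_dD)
        samples.append(
            WaterSample(
                sample_id=f"precip-{i:03d}",
                kind=SampleKind.PRECIPITATION,
                date=date,
                treatment="",
                d18O_permil=d18O,
                dD_permil=float(dD),
                amount_mm=amount,
            )
        )
    return samples


def generate_weather(config: SyntheticConfig) -> list[WeatherDay]:
    """A daily weather series within the configured physical ranges."""
    rng = config.rng("weather")
    days: list[WeatherDay] = []
    for i in range(config.n_weather_days):
        date = config.start_date + _dt.timedelta(days=i)
        T = float(rng.uniform(*config.T_range))
        days.append(
            WeatherDay.from_relative_humidity(
                date=date,
                Rn=float(rng.uniform(*config.Rn_range)),
                G=float(rng.uniform(*config.G_range)),
                T_mean=T,
                u2=float(rng.uniform(*config.u2_range)),
                RH_mean_pct=float(rng.uniform(*config.RH_range)),
            )
        )
    return days


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full dataset; optionally write the four CSVs + truth JSON."""
    soil = generate_soil_profiles(config)
    stem = generate_stem_samples(config, soil)
    precip = generate_precipitation(config)
    water = soil + stem + precip
    rld = generate_rld_profiles(config)
    uptake = generate_uptake_points(config)
    weather = generate_weather(config)
    truth = {
        "seed": config.seed,
        "layer_bounds": [list(b) for b in config.layer_bounds],
        "true_fractions": {
            f"{d}|{t}": list(f) for (d, t), f in _group_fractions(config).items()
        },
        "lmwl": {"slope": config.lmwl_slope, "intercept": config.lmwl_intercept},
        "evap_line": {"slope": config.evap_slope, "intercept": config.evap_intercept},
        "soil_profile": {
            "d18O_surface": config.d18O_surface,
            "gradient_permil_per_cm": config.profile_gradient_permil_per_cm,
            "surface_enrichment_permil": config.surface_enrichment_permil,
            "enrichment_efold_cm": config.enrichment_efold_cm,
        },
        "uptake": {"k": config.uptake_k, "A": config.uptake_A},
        "rld_decay_per_cm": config.rld_decay_per_cm,
    }
    ds = SyntheticDataset(config, water, rld, uptake, weather, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_water_samples(water, out / "water_samples.csv")
        rld.to_csv(out / "rld.csv", index=False)
        write_weather(weather, out / "weather.csv")
        pd.DataFrame(uptake, columns=["S", "y"]).to_csv(out / "uptake_points.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return ds
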