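"""Group-wise pipeline stages over long-format sample tables.

Per-sample analyses (mixing model, intersection method) run independently
for each (date, treatment) group, matching a sampling design of repeated
dates across factorial treatments.  Precipitation-based stages first drop
small events (default > 5 mm retained), which are hard to sample and prone
to strong fractionation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .isotopes import MeteoricLine, SampleKind, WaterSample, fit_meteoric_line
from .mixing import DEFAULT_LAYER_BOUNDS, MCMCConfig, IsotopeMixingModel
from .profiles import AmbiguousUptakeDepth, profile_from_samples, single_uptake_depth
from .rld import RLDProfile

logger = logging.getLogger("isopart")

__all__ = [
    "filter_precipitation",
    "lmwl_from_precipitation",
    "group_samples",
    "mix_all_groups",
    "uptake_depths_all_groups",
    "pool_uptake_vs_rld",
]

PRECIP_MIN_EVENT_MM = 5.0


def filter_precipitation(
    samples: Sequence[WaterSample], min_event_mm: float = PRECIP_MIN_EVENT_MM
) -> list[WaterSample]:
    """Keep precipitation events strictly above the small-event threshold."""
    events = [s for s in samples if s.kind is SampleKind.PRECIPITATION]
    kept = [s for s in events if s.amount_mm is not None and s.amount_mm > min_event_mm]
    logger.info(
        "precipitation filter >%g mm: kept %d of %d events", min_event_mm, len(kept), len(events)
    )
    return kept


def lmwl_from_precipitation(
    samples: Sequence[WaterSample], min_event_mm: float = PRECIP_MIN_EVENT_MM
) -> tuple[MeteoricLine, int]:
    """Local meteoric water line from filtered precipitation events."""
    kept = filter_precipitation(samples, min_event_mm)
    line = fit_meteoric_line([(s.d18O_permil, s.dD_permil) for s in kept])
    return line, len(kept)


def group_samples(
    samples: Sequence[WaterSample],
) -> dict[tuple[str, str], list[WaterSample]]:
    """Samples keyed by (ISO date, treatment), sorted for determinism."""
    groups: dict[tuple[str, str], list[WaterSample]] = {}
    for s in samples:
        groups.setdefault((s.date.isoformat(), s.treatment), []).append(s)
    return dict(sorted(groups.items()))


def mix_all_groups(
    samples: Sequence[WaterSample],
    layer_bounds: Sequence[tuple[float, float]] = DEFAULT_LAYER_BOUNDS,
    mcmc: MCMCConfig | None = None,
) -> pd.DataFrame:
    """Fit the mixing model per (date, treatment); one output row per layer.

    Each group needs exactly soil samples covering every layer and at least
    one stem sample (averaged if several).  Groups missing either are
    skipped with a warning.  Group seeds are derived deterministically from
    the configured seed so groups are independent yet reproducible.
    """
    mcmc = mcmc or MCMCConfig()
    rows = []
    groups = group_samples(
        [s for s in samples if s.kind in (SampleKind.SOIL, SampleKind.STEM)]
    )
    seed_seq = np.random.SeedSequence(mcmc.seed)
    group_seeds = [int(s) for s in seed_seq.generate_state(max(len(groups), 1)) >> 1]
    for (key, group), g_seed in zip(groups.items(), group_seeds):
        date, trt = key
        soils = [s for s in group if s.kind is SampleKind.SOIL]
        stems = [s for s in group if s.kind is SampleKind.STEM]
        if not soils or not stems:
            logger.warning("group %s: missing soil or stem samples, skipped", key)
            continue
        stem_mean = WaterSample(
            sample_id=f"stem-mean-{date}-{trt}",
            kind=SampleKind.STEM,
            date=stems[0].date,
            treatment=trt,
            d18O_permil=float(np.mean([s.d18O_permil for s in stems])),
            dD_permil=float(np.mean([s.dD_permil for s in stems])),
        )
        model = IsotopeMixingModel.from_samples(stem_mean, soils, layer_bounds)
        res = model.fit(mcmc, seed=g_seed)
        summ = res.summary()
        for rec in summ.to_dict("records"):
            rows.append({"date": date, "treatment": trt, **rec})
        logger.info("group %s: mixing model fitted (%d layers)", key, len(summ))
    return pd.DataFrame(rows)


def uptake_depths_all_groups(
    samples: Sequence[WaterSample],
    isotope: str = "d18O",
    policy: str = "strict",
) -> pd.DataFrame:
    """Intersection-method uptake depth per (date, treatment) group."""
    rows = []
    plant_soil = [s for s in samples if s.kind in (SampleKind.SOIL, SampleKind.STEM)]
    for (date, trt), group in group_samples(plant_soil).items():
        soils = [s for s in group if s.kind is SampleKind.SOIL]
        stems = [s for s in group if s.kind is SampleKind.STEM]
        if len(soils) < 2 or not stems:
            logger.warning("group %s: insufficient samples for profile, skipped", (date, trt))
            continue
        profile = profile_from_samples(soils, isotope)
        stem_value = float(
            np.mean([s.d18O_permil if isotope == "d18O" else s.dD_permil for s in stems])
        )
        flags = []
        try:
            crossing = single_uptake_depth(profile, stem_value, policy)
            depth = crossing.depth_cm
            n_crossings = 1 if policy == "strict" else None
            if crossing.flat_segment:
                flags.append("flat_segment")
        except AmbiguousUptakeDepth as exc:
            depth = np.nan
            n_crossings = len(exc.crossings)
            flags.append("no_crossing" if not exc.crossings else "multiple_crossings")
        if n_crossings is None:
            from .profiles import find_uptake_depths

            n_crossings = len(find_uptake_depths(profile, stem_value))
            if n_crossings > 1:
                flags.append("multiple_crossings")
        rows.append(
            {
                "date": date,
                "treatment": trt,
                "isotope": isotope,
                "n_crossings": n_crossings,
                "depth_cm": depth,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def pool_uptake_vs_rld(
    mix_summary: pd.DataFrame,
    rld_profiles: dict[tuple, RLDProfile],
    layer_bounds: Sequence[tuple[float, float]] = DEFAULT_LAYER_BOUNDS,
    s_scale: float = 1000.0,
    y_scale: float = 1000.0,
) -> list[tuple[float, float]]:
    """Pool (normalized RLD, uptake fraction) pairs across groups and layers.

    RLD bins are aggregated to the mixing-model layers by bin-midpoint
    membership; a mixing-model row for (date, treatment, layer) is paired
    with the matching group's layer-aggregated normalized RLD.  Both axes
    are scaled (default ×1000) to a per-mil-style convention so saturation
    appears at interpretable magnitudes.
    """
    bounds = [(float(t), float(b)) for t, b in layer_bounds]
    labels = [f"{t:g}-{b:g}cm" for t, b in bounds]
    points: list[tuple[float, float]] = []
    for (date, trt, *_), prof in sorted(rld_profiles.items()):
        mids = prof.bin_mids_cm
        layer_rld = {}
        for (top, bottom), label in zip(bounds, labels):
            frac = sum(
                f for m, f in zip(mids, prof.normalized) if top <= m < bottom
            )
            layer_rld[label] = frac
        sub = mix_summary[(mix_summary["date"] == date) & (mix_summary["treatment"] == trt)]
        for rec in sub.to_dict("records"):
            if rec["layer"] in layer_rld:
                points.append(
                    (s_scale * layer_rld[rec["layer"]], y_scale * float(rec["mean"]))
                )
    return points
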