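"""δ-notation arithmetic, meteoric-water-line regression and soil-water grouping.

Stable water isotope abundances are expressed throughout in per-mil (‰)
δ-notation relative to VSMOW (Vienna Standard Mean Ocean Water):

    δ = (R_sample / R_VSMOW − 1) × 1000

where R is the heavy/light abundance ratio (¹⁸O/¹⁶O or ²H/¹H).  Raw ratios
appear only at this conversion boundary; every other function in the package
takes and returns ‰ values, which avoids 1e-3 scale bugs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "SampleKind",
    "WaterSample",
    "MeteoricLine",
    "delta_from_ratio",
    "delta_to_ratio",
    "fit_meteoric_line",
    "split_soil_water_groups",
]

# Plausibility windows (‰ VSMOW) for accepting a measurement.
D18O_WINDOW = (-100.0, 50.0)
DD_WINDOW = (-500.0, 100.0)


class SampleKind(str, Enum):
    STEM = "stem"
    SOIL = "soil"
    PRECIPITATION = "precipitation"
    IRRIGATION = "irrigation"


@dataclass(frozen=True)
class WaterSample:
    """One water sample with its paired δ¹⁸O / δD measurement.

    ``depth_cm`` is required for soil samples and must be absent otherwise;
    ``amount_mm`` is the event depth for precipitation samples.
    """

    sample_id: str
    kind: SampleKind
    date: _dt.date
    treatment: str
    d18O_permil: float
    dD_permil: float
    depth_cm: float | None = None
    amount_mm: float | None = None

    def __post_init__(self) -> None:
        kind = SampleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is SampleKind.SOIL:
            if self.depth_cm is None:
                raise ValueError(f"soil sample {self.sample_id!r} requires depth_cm")
            if self.depth_cm < 0:
                raise ValueError("depth_cm must be non-negative")
        elif self.depth_cm is not None:
            raise ValueError(f"{kind.value} sample {self.sample_id!r} must not carry depth_cm")
        for name, value, (lo, hi) in (
            ("d18O_permil", self.d18O_permil, D18O_WINDOW),
            ("dD_permil", self.dD_permil, DD_WINDOW),
        ):
            if not np.isfinite(value):
                raise ValueError(f"{name} of {self.sample_id!r} is not finite")
            if not lo <= value <= hi:
                raise ValueError(
                    f"{name}={value} ‰ of {self.sample_id!r} outside plausibility window [{lo}, {hi}]"
                )
        if self.amount_mm is not None and self.amount_mm < 0:
            raise ValueError("amount_mm must be non-negative")


@dataclass(frozen=True)
class MeteoricLine:
    """A fitted δD = slope·δ¹⁸O + intercept line (OLS of δD on δ¹⁸O)."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a meteoric line needs n >= 2 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, d18O_permil: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(d18O_permil) + self.intercept


#: Global meteoric water line, δD = 8·δ¹⁸O + 10 (Craig).
GMWL = MeteoricLine(slope=8.0, intercept=10.0, r_squared=1.0, n=2)


def delta_from_ratio(r_sample: float, r_reference: float) -> float:
    """Convert an abundance ratio to ‰ δ-notation against a reference ratio."""
    if r_sample <= 0 or r_reference <= 0:
        raise ValueError("abundance ratios must be positive")
    return (r_sample / r_reference - 1.0) * 1000.0


def delta_to_ratio(delta_permil: float, r_reference: float = 1.0) -> float:
    """Inverse of :func:`delta_from_ratio`; δ must exceed −1000 ‰."""
    if delta_permil <= -1000.0:
        raise ValueError("delta must exceed -1000 permil")
    return r_reference * (1.0 + delta_permil / 1000.0)


def fit_meteoric_line(pairs: Iterable[tuple[float, float]]) -> MeteoricLine:
    """Ordinary least squares of δD on δ¹⁸O over (δ¹⁸O, δD) pairs.

    Returns the y-on-x slope/intercept/R² form in which meteoric water lines
    are conventionally reported.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (d18O, dD) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in d18O: meteoric line is undefined")
    res = _stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    # guard fp round-off on exactly collinear input
    r2 = min(max(r2, 0.0), 1.0)
    return MeteoricLine(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2, n=len(x))


def split_soil_water_groups(
    samples: Sequence[WaterSample], threshold_d18O: float = -10.0
) -> tuple[list[WaterSample], list[WaterSample]]:
    """Partition soil samples by δ¹⁸O strictly above vs. at-or-below a threshold.

    Shallow soil water enriched by evaporation plots above roughly −10 ‰ δ¹⁸O
    and follows the stem-water δD–δ¹⁸O relationship; depleted deep water falls
    below it.  A sample exactly on the threshold goes to the *below* group
    (strict inequality defines "above").
    """
    for s in samples:
        if s.kind is not SampleKind.SOIL:
            raise ValueError(f"non-soil sample {s.sample_id!r} in soil-water grouping")
    above = [s for s in samples if s.d18O_permil > threshold_d18O]
    below = [s for s in samples if s.d18O_permil <= threshold_d18O]
    return above, below
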