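"""Uptake-depth estimation by the intersection method.

Plotting the stem-water isotope value as a vertical line against the soil
isotope–depth profile, the depth(s) at which the two cross indicate where the
roots took up water.  The soil profile is interpolated piecewise-linearly
between the measured depths — with only ~7 sampling depths, splines would
invent extrema and hence spurious crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .isotopes import SampleKind, WaterSample

__all__ = [
    "DepthProfile",
    "Crossing",
    "AmbiguousUptakeDepth",
    "interpolate",
    "find_uptake_depths",
    "single_uptake_depth",
    "profile_from_samples",
]

Isotope = Literal["d18O", "dD"]


@dataclass(frozen=True)
class DepthProfile:
    """An ordered isotope-vs-depth profile (depths strictly increasing)."""

    depths_cm: tuple[float, ...]
    values_permil: tuple[float, ...]
    isotope: Isotope = "d18O"

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_cm, dtype=float)
        v = np.asarray(self.values_permil, dtype=float)
        if d.size < 2 or d.size != v.size:
            raise ValueError("profile needs >= 2 (depth, value) points of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "depths_cm", tuple(float(x) for x in d))
        object.__setattr__(self, "values_permil", tuple(float(x) for x in v))


@dataclass(frozen=True)
class Crossing:
    depth_cm: float
    flat_segment: bool = False


class AmbiguousUptakeDepth(ValueError):
    """Raised when the strict policy finds zero or several crossings."""

    def __init__(self, crossings: list[Crossing], message: str):
        super().__init__(message)
        self.crossings = crossings


def profile_from_samples(
    soil_samples: Sequence[WaterSample], isotope: Isotope = "d18O"
) -> DepthProfile:
    """Build a depth profile from soil samples of one (date, treatment) group."""
    soils = [s for s in soil_samples if s.kind is SampleKind.SOIL]
    if len(soils) != len(soil_samples):
        raise ValueError("profile_from_samples accepts soil samples only")
    by_depth: dict[float, list[float]] = {}
    for s in soils:
        val = s.d18O_permil if isotope == "d18O" else s.dD_permil
        by_depth.setdefault(float(s.depth_cm), []).append(val)
    depths = sorted(by_depth)
    values = [float(np.mean(by_depth[d])) for d in depths]
    return DepthProfile(tuple(depths), tuple(values), isotope)


def interpolate(profile: DepthProfile, depth_cm: float) -> float:
    """Piecewise-linear profile value at a depth; no extrapolation."""
    d = np.asarray(profile.depths_cm)
    if not d[0] <= depth_cm <= d[-1]:
        raise ValueError(
            f"depth {depth_cm} cm outside profile range [{d[0]}, {d[-1]}] cm (no extrapolation)"
        )
    return float(np.interp(depth_cm, d, np.asarray(profile.values_permil)))


def find_uptake_depths(profile: DepthProfile, stem_value: float) -> list[Crossing]:
    """All depths where the interpolated profile equals the stem value, ascending.

    A segment lying entirely on the stem value reports its midpoint, flagged
    as flat.  A node the profile merely touches (adjacent segments on the
    same side) still counts as one crossing, matching a graphical reading.
    """
    d = np.asarray(profile.depths_cm)
    v = np.asarray(profile.values_permil) - stem_value
    n = len(d)
    crossings: list[Crossing] = []

    # flat segments: both endpoints on the stem value
    for i in range(n - 1):
        if v[i] == 0.0 and v[i + 1] == 0.0:
            crossings.append(Crossing(float((d[i] + d[i + 1]) / 2.0), flat_segment=True))
    # isolated zero nodes (a node touching the stem value, no flat neighbour)
    for k in range(n):
        if v[k] == 0.0 and (k == 0 or v[k - 1] != 0.0) and (k == n - 1 or v[k + 1] != 0.0):
            crossings.append(Crossing(float(d[k])))
    # strict sign changes within a segment
    for i in range(n - 1):
        if v[i] * v[i + 1] < 0.0:
            t = v[i] / (v[i] - v[i + 1])
            crossings.append(Crossing(float(d[i] + t * (d[i + 1] - d[i]))))

    return sorted(crossings, key=lambda c: c.depth_cm)


def single_uptake_depth(
    profile: DepthProfile,
    stem_value: float,
    policy: Literal["strict", "shallowest"] = "strict",
) -> Crossing:
    """The uptake depth under an ambiguity policy.

    ``strict`` errors unless exactly one crossing exists; ``shallowest``
    returns the first (shallowest) crossing, erroring only when there is none.
    """
    crossings = find_uptake_depths(profile, stem_value)
    if not crossings:
        raise AmbiguousUptakeDepth(
            crossings, f"no intersection of stem value {stem_value} ‰ with the profile"
        )
    if policy == "strict":
        if len(crossings) > 1:
            depths = [round(c.depth_cm, 4) for c in crossings]
            raise AmbiguousUptakeDepth(
                crossings,
                f"{len(crossings)} intersections at depths {depths} cm under strict policy",
            )
        return crossings[0]
    if policy == "shallowest":
        return crossings[0]
    raise ValueError(f"unknown policy {policy!r}")
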