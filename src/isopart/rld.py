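"""Root-length-density profiles and the saturating uptake–RLD relationship.

Root water uptake from a soil region grows with root-length density (RLD)
but saturates where roots are dense enough to compete for water.  Pooled
over treatments and dates, uptake rate *y* versus normalized RLD *S* follows
a Michaelis–Menten-type curve

    y = k·S / (A + S)

with asymptote *k* and half-saturation constant *A* (the *S* at which
y = k/2).  The fit is nonlinear least squares initialised from the
double-reciprocal (Lineweaver–Burk) linearisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "CORE_VOLUME_CM3",
    "RLDProfile",
    "SaturatingFit",
    "SaturatingUptakeModel",
    "normalize_rld",
    "saturating_model",
    "fit_saturating",
]

#: Volume of the soil core from which root lengths are measured (cm³); the
#: divisor when absolute RLD (cm cm⁻³) rather than normalized RLD is wanted.
CORE_VOLUME_CM3 = 375.0

DEFAULT_BIN_TOPS = tuple(float(t) for t in range(0, 100, 10))


@dataclass(frozen=True)
class RLDProfile:
    """Root lengths per 10-cm depth bin and their profile-normalized fractions."""

    bin_tops_cm: tuple[float, ...]
    lengths_cm: tuple[float, ...]
    normalized: tuple[float, ...]

    def __post_init__(self) -> None:
        tops = np.asarray(self.bin_tops_cm)
        if np.any(np.diff(tops) <= 0):
            raise ValueError("bin tops must be strictly increasing")
        if len(self.lengths_cm) != len(tops) or len(self.normalized) != len(tops):
            raise ValueError("lengths/normalized must match bin count")
        total = sum(self.normalized)
        if sum(self.lengths_cm) > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("normalized fractions must sum to 1")

    @property
    def bin_mids_cm(self) -> tuple[float, ...]:
        tops = list(self.bin_tops_cm)
        widths = [b - a for a, b in zip(tops, tops[1:])]
        widths.append(widths[-1] if widths else 10.0)
        return tuple(t + w / 2.0 for t, w in zip(tops, widths))

    def rld_cm_per_cm3(self, core_volume_cm3: float = CORE_VOLUME_CM3) -> tuple[float, ...]:
        """Absolute root-length density per bin (cm root per cm³ soil)."""
        return tuple(length / core_volume_cm3 for length in self.lengths_cm)


def normalize_rld(
    lengths_cm: Sequence[float], bin_tops_cm: Sequence[float] = DEFAULT_BIN_TOPS
) -> RLDProfile:
    """Normalize per-bin root lengths by the profile total."""
    lengths = np.asarray(lengths_cm, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("root lengths must be non-negative")
    total = lengths.sum()
    if total == 0:
        raise ValueError("degenerate RLD profile: total root length is zero")
    return RLDProfile(
        bin_tops_cm=tuple(float(t) for t in bin_tops_cm),
        lengths_cm=tuple(float(x) for x in lengths),
        normalized=tuple(float(x) for x in lengths / total),
    )


def saturating_model(S, k: float, A: float):
    """Saturating uptake curve y = kS/(A+S)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    if k <= 0 or A <= 0:
        raise ValueError("k and A must be > 0")
    out = k * S / (A + S)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SaturatingFit:
    """Converged parameters of the saturating uptake fit."""

    k: float
    A: float
    rss: float
    n: int

    def __post_init__(self) -> None:
        if self.k <= 0 or self.A <= 0:
            raise ValueError("fitted k and A must be > 0")

    def predict(self, S):
        return saturating_model(S, self.k, self.A)


class SaturatingUptakeModel:
    """Nonlinear least-squares fit of uptake rate against normalized RLD."""

    def __init__(self, S: Sequence[float], y: Sequence[float]):
        S = np.asarray(S, dtype=float)
        y = np.asarray(y, dtype=float)
        if S.size != y.size or S.size < 3:
            raise ValueError("need >= 3 (S, y) points")
        if len(np.unique(S[S > 0])) < 2:
            raise ValueError("need >= 2 distinct S > 0")
        if np.all(y == 0):
            raise ValueError("degenerate data: all uptake rates are zero")
        self.S, self.y = S, y

    def _initial_guess(self) -> tuple[float, float]:
        # Lineweaver-Burk: 1/y = (A/k)(1/S) + 1/k, on points with S, y > 0
        mask = (self.S > 0) & (self.y > 0)
        if mask.sum() >= 2:
            inv = linregress(1.0 / self.S[mask], 1.0 / self.y[mask])
            if inv.intercept > 0 and inv.slope > 0:
                k0 = 1.0 / inv.intercept
                return k0, inv.slope * k0
        return 2.0 * float(self.y.max()), float(np.median(self.S[self.S > 0]))

    def fit(self) -> SaturatingFit:
        k0, A0 = self._initial_guess()
        try:
            popt, _ = curve_fit(
                lambda S, k, A: k * S / (A + S),
                self.S,
                self.y,
                p0=(k0, A0),
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise RuntimeError(
                f"saturating fit failed to converge (p0=({k0:.4g}, {A0:.4g})): {exc}"
            ) from exc
        k, A = float(popt[0]), float(popt[1])
        rss = float(np.sum((self.y - saturating_model(self.S, k, A)) ** 2))
        return SaturatingFit(k=k, A=A, rss=rss, n=int(self.S.size))


def fit_saturating(points: Sequence[tuple[float, float]]) -> SaturatingFit:
    """Fit y = kS/(A+S) to (S, y) points."""
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (S, y) pairs")
    return SaturatingUptakeModel(arr[:, 0], arr[:, 1]).fit()
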