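"""Bayesian isotope mass-balance mixing model for root water uptake.

Stem water is modelled as a convex mixture of soil-layer source waters:

    δD_stem   = Σ_i f_i · δD_i
    δ¹⁸O_stem = Σ_i f_i · δ¹⁸O_i        with  Σ_i f_i = 1,  f_i ≥ 0

where ``f_i`` is the fraction of transpiration drawn from layer *i*.  With
four layers and two measured isotopes the system is under-determined, so the
fractions are inferred in a Bayesian way: a symmetric Dirichlet prior on the
simplex times a Gaussian likelihood for the measured stem isotopes, sampled
by random-walk Metropolis in log-ratio coordinates.

The likelihood variance for isotope *t* is either the measurement variance
alone (``measurement_only``) or, by default, the SIAR-style propagated form

    σ_t² = σ_meas,t² + Σ_i f_i² · sd_{t,i}²

which carries the within-layer source spread into the mixture.

Usage follows the Model/Results convention::

    model = IsotopeMixingModel(obs, sources)
    res = model.fit(MCMCConfig(seed=1))
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .isotopes import SampleKind, WaterSample

__all__ = [
    "SourceLayer",
    "MixtureObservation",
    "MCMCConfig",
    "MixingResults",
    "IsotopeMixingModel",
    "DEFAULT_LAYER_BOUNDS",
    "GAPPED_LAYER_BOUNDS",
    "build_sources",
    "predict_mixture",
    "log_likelihood",
    "sample_posterior",
    "summarize_posterior",
]

#: Default four-layer scheme (cm), covering the whole 0-100 cm profile.
DEFAULT_LAYER_BOUNDS: tuple[tuple[float, float], ...] = ((0, 5), (5, 20), (20, 60), (60, 100))

#: Gapped variant of the scheme that leaves 60-80 cm unmonitored and uses
#: only 80-100 cm as the deep source.
GAPPED_LAYER_BOUNDS: tuple[tuple[float, float], ...] = ((0, 5), (5, 20), (20, 60), (80, 100))


@dataclass(frozen=True)
class SourceLayer:
    """Per-layer source water distribution (mean, sd, n for each isotope)."""

    label: str
    top_cm: float
    bottom_cm: float
    mean_d18O: float
    sd_d18O: float
    mean_dD: float
    sd_dD: float
    n: int

    def __post_init__(self) -> None:
        if self.top_cm >= self.bottom_cm:
            raise ValueError(f"layer {self.label!r}: top_cm must be < bottom_cm")
        if self.sd_d18O < 0 or self.sd_dD < 0:
            raise ValueError(f"layer {self.label!r}: sds must be >= 0")
        if self.n < 1:
            raise ValueError(f"layer {self.label!r}: n must be >= 1")


@dataclass(frozen=True)
class MixtureObservation:
    """A measured stem-water isotope pair with its measurement uncertainty.

    Default sigmas are the analyser precisions: ±0.1 ‰ for δ¹⁸O and
    ±1.4 ‰ for δD.
    """

    d18O: float
    dD: float
    sigma_d18O: float = 0.1
    sigma_dD: float = 1.4

    def __post_init__(self) -> None:
        if self.sigma_d18O <= 0 or self.sigma_dD <= 0:
            raise ValueError("measurement sigmas must be > 0")


VarianceMode = Literal["measurement_only", "siar_propagated"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``n_iter`` counts iterations per chain."""

    n_chains: int = 4
    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    dirichlet_alpha: float = 1.0
    variance_mode: VarianceMode = "siar_propagated"

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter, self.burn_in, self.thin) < 1:
            raise ValueError("all MCMC counts must be >= 1")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")
        if self.variance_mode not in ("measurement_only", "siar_propagated"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")


def build_sources(
    soil_samples: Sequence[WaterSample],
    layer_bounds: Sequence[tuple[float, float]] = DEFAULT_LAYER_BOUNDS,
) -> list[SourceLayer]:
    """Aggregate soil samples into per-layer source distributions.

    Depth membership is lower-open, upper-closed (top, bottom] — a sample
    cored at exactly 20 cm caps the 5–20 cm layer — with the first layer
    additionally including its own top.  This maps the campaign's sampling
    depths 5, 10, 20, 40, 60, 80, 100 cm onto the four-layer scheme with no
    empty layer.  Sample sd (ddof=1) is used; sd = 0 when a layer holds a
    single sample.  An empty layer is a configuration error.
    """
    bounds = [(float(t), float(b)) for t, b in layer_bounds]
    if sorted(bounds) != bounds or any(
        b1[1] > b2[0] + 1e-12 for b1, b2 in zip(bounds, bounds[1:])
    ):
        raise ValueError("layer bounds must be sorted and non-overlapping")
    for s in soil_samples:
        if s.kind is not SampleKind.SOIL:
            raise ValueError(f"non-soil sample {s.sample_id!r} passed to build_sources")
    out: list[SourceLayer] = []
    for j, (top, bottom) in enumerate(bounds):
        members = [
            s
            for s in soil_samples
            if top < s.depth_cm <= bottom or (j == 0 and s.depth_cm == top)
        ]
        label = f"{top:g}-{bottom:g}cm"
        if not members:
            raise ValueError(f"layer {label} received no soil samples")
        d18O = np.array([s.d18O_permil for s in members])
        dD = np.array([s.dD_permil for s in members])
        n = len(members)
        out.append(
            SourceLayer(
                label=label,
                top_cm=top,
                bottom_cm=bottom,
                mean_d18O=float(d18O.mean()),
                sd_d18O=float(d18O.std(ddof=1)) if n > 1 else 0.0,
                mean_dD=float(dD.mean()),
                sd_dD=float(dD.std(ddof=1)) if n > 1 else 0.0,
                n=n,
            )
        )
    return out


def _source_arrays(sources: Sequence[SourceLayer]) -> tuple[np.ndarray, np.ndarray]:
    """Means and sds stacked as (N, 2) arrays with columns (d18O, dD)."""
    means = np.array([[s.mean_d18O, s.mean_dD] for s in sources])
    sds = np.array([[s.sd_d18O, s.sd_dD] for s in sources])
    return means, sds


def _check_simplex(f: np.ndarray, n: int, tol: float = 1e-9) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (n,):
        raise ValueError(f"fraction vector must have length {n}")
    if np.any(f < -tol) or abs(f.sum() - 1.0) > tol:
        raise ValueError("fraction vector is off the simplex")
    return np.clip(f, 0.0, None)


def predict_mixture(
    f: Sequence[float], sources: Sequence[SourceLayer]
) -> tuple[float, float]:
    """Mixture isotope values (δ¹⁸O, δD) for uptake fractions ``f``."""
    fv = _check_simplex(np.asarray(f, dtype=float), len(sources))
    means, _ = _source_arrays(sources)
    pred = fv @ means
    return float(pred[0]), float(pred[1])


def _loglik_batch(
    F: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    y: np.ndarray,
    sigma2_meas: np.ndarray,
    propagated: bool,
) -> np.ndarray:
    """Gaussian log-likelihood for a batch of fraction vectors F (m, N)."""
    pred = F @ means  # (m, 2)
    var = np.broadcast_to(sigma2_meas, pred.shape).copy()
    if propagated:
        var = var + (F**2) @ (sds**2)
    resid = y - pred
    return np.sum(-0.5 * np.log(2.0 * np.pi * var) - 0.5 * resid**2 / var, axis=1)


def log_likelihood(
    f: Sequence[float],
    sources: Sequence[SourceLayer],
    obs: MixtureObservation,
    variance_mode: VarianceMode = "siar_propagated",
) -> float:
    """Log-density of the observed stem isotopes given fractions ``f``.

    Both isotopes are treated as independent Gaussians around the mixture
    prediction, with per-isotope variance selected by ``variance_mode``.
    """
    fv = _check_simplex(np.asarray(f, dtype=float), len(sources))
    means, sds = _source_arrays(sources)
    y = np.array([obs.d18O, obs.dD])
    sigma2 = np.array([obs.sigma_d18O**2, obs.sigma_dD**2])
    propagated = variance_mode == "siar_propagated"
    var = sigma2 + ((fv**2) @ (sds**2) if propagated else 0.0)
    if np.any(var <= 0):
        raise ValueError("zero total variance: likelihood undefined")
    return float(_loglik_batch(fv[None, :], means, sds, y, sigma2, propagated)[0])


def _softmax_alr(z: np.ndarray) -> np.ndarray:
    """Map ALR coordinates (m, N-1) to simplex fractions (m, N)."""
    z_full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    z_full -= z_full.max(axis=1, keepdims=True)
    e = np.exp(z_full)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MixingResults:
    """Posterior of the layer uptake fractions.

    ``draws`` stacks all retained post-burn-in draws across chains, each row
    on the simplex.  Convergence diagnostics (rhat, ess) are per component.
    """

    layer_labels: list[str]
    draws: np.ndarray  # (n_kept, N)
    chain_draws: np.ndarray  # (n_chains, n_kept_per_chain, N)
    mean: np.ndarray
    ci_95: np.ndarray  # (N, 2)
    rhat: np.ndarray
    ess: np.ndarray
    acceptance_rate: float
    config: MCMCConfig
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: one row per layer."""
        if self.draws.size == 0:
            raise ValueError("empty posterior draws")
        means = self.draws.mean(axis=0)
        if abs(means.sum() - 1.0) > 1e-9:
            raise AssertionError("posterior means do not sum to 1")
        return pd.DataFrame(
            {
                "layer": self.layer_labels,
                "mean": means,
                "lo95": self.ci_95[:, 0],
                "hi95": self.ci_95[:, 1],
                "rhat": self.rhat,
                "ess": self.ess,
            }
        )


class IsotopeMixingModel:
    """Bayesian mixing model for one stem observation against layered sources.

    Parameters
    ----------
    obs : MixtureObservation
        Measured stem-water δ¹⁸O and δD with their measurement sigmas.
    sources : sequence of SourceLayer
        At least two soil-layer source distributions, sorted by depth.
    """

    def __init__(self, obs: MixtureObservation, sources: Sequence[SourceLayer]):
        if len(sources) < 2:
            raise ValueError("need at least 2 source layers")
        tops = [s.top_cm for s in sources]
        if tops != sorted(tops):
            raise ValueError("sources must be sorted by top_cm")
        self.obs = obs
        self.sources = list(sources)
        self.n_layers = len(sources)
        self._means, self._sds = _source_arrays(sources)

    @classmethod
    def from_samples(
        cls,
        stem_sample: WaterSample,
        soil_samples: Sequence[WaterSample],
        layer_bounds: Sequence[tuple[float, float]] = DEFAULT_LAYER_BOUNDS,
        sigma_d18O: float = 0.1,
        sigma_dD: float = 1.4,
    ) -> "IsotopeMixingModel":
        """Build the model directly from water samples of one (date, treatment)."""
        obs = MixtureObservation(
            d18O=stem_sample.d18O_permil,
            dD=stem_sample.dD_permil,
            sigma_d18O=sigma_d18O,
            sigma_dD=sigma_dD,
        )
        return cls(obs, build_sources(soil_samples, layer_bounds))

    # -- target density -------------------------------------------------

    def _log_target_z(self, z: np.ndarray, config: MCMCConfig) -> tuple[np.ndarray, np.ndarray]:
        """Unnormalised log posterior in ALR coordinates, with Jacobian.

        The softmax map z -> f has Jacobian determinant ∏_i f_i, so the
        z-space density is  Dirichlet(α) · L(f|Y) · ∏ f_i, i.e. the
        (α-1)·Σlog f_i prior term becomes α·Σlog f_i.
        """
        F = _softmax_alr(z)
        logf = np.log(np.clip(F, 1e-300, None)).sum(axis=1)
        y = np.array([self.obs.d18O, self.obs.dD])
        sigma2 = np.array([self.obs.sigma_d18O**2, self.obs.sigma_dD**2])
        ll = _loglik_batch(
            F, self._means, self._sds, y, sigma2, config.variance_mode == "siar_propagated"
        )
        return ll + config.dirichlet_alpha * logf, F

    # -- sampling --------------------------------------------------------

    def fit(self, config: MCMCConfig | None = None, **overrides) -> MixingResults:
        """Sample the posterior of the uptake fractions.

        Random-walk Metropolis in additive-log-ratio coordinates, all chains
        advanced in lockstep; the per-chain step size is adapted during
        burn-in toward a 20–50 % acceptance rate and then frozen.  Fully
        reproducible given ``config.seed``.
        """
        config = config or MCMCConfig()
        if overrides:
            config = replace(config, **overrides)
        rng = np.random.default_rng(config.seed)
        C, N = config.n_chains, self.n_layers
        dim = N - 1

        z = rng.normal(0.0, 1.0, size=(C, dim))
        logp, _ = self._log_target_z(z, config)
        step = np.full(C, 0.5)
        accept_win = np.zeros(C)
        accepted_post = 0
        proposals_post = 0
        adapt_every = 50

        kept_per_chain = (config.n_iter - config.burn_in) // config.thin
        kept = np.empty((C, kept_per_chain, N))
        k = 0

        for it in range(config.n_iter):
            prop = z + step[:, None] * rng.normal(size=(C, dim))
            logp_prop, F_prop = self._log_target_z(prop, config)
            accept = np.log(rng.random(C)) < (logp_prop - logp)
            z[accept] = prop[accept]
            logp[accept] = logp_prop[accept]
            if it < config.burn_in:
                accept_win += accept
                if (it + 1) % adapt_every == 0:
                    rate = accept_win / adapt_every
                    # Robbins-Monro toward ~30 % acceptance
                    step *= np.exp((rate - 0.30))
                    accept_win[:] = 0.0
            else:
                accepted_post += int(accept.sum())
                proposals_post += C
                if (it - config.burn_in) % config.thin == config.thin - 1 and k < kept_per_chain:
                    kept[:, k, :] = _softmax_alr(z)
                    k += 1

        kept = kept[:, :k, :]
        draws = kept.reshape(-1, N)
        # retained draws live exactly on the simplex
        draws = draws / draws.sum(axis=1, keepdims=True)
        kept = kept / kept.sum(axis=2, keepdims=True)

        mean = draws.mean(axis=0)
        ci = np.quantile(draws, [0.025, 0.975], axis=0).T
        rhat, ess = self._diagnostics(kept)
        warn: list[str] = []
        if np.any(rhat > 1.1):
            bad = [self._labels()[i] for i in np.where(rhat > 1.1)[0]]
            msg = f"convergence warning: rhat > 1.1 for layers {bad}"
            warn.append(msg)
            _warnings.warn(msg, RuntimeWarning, stacklevel=2)

        return MixingResults(
            layer_labels=self._labels(),
            draws=draws,
            chain_draws=kept,
            mean=mean,
            ci_95=ci,
            rhat=rhat,
            ess=ess,
            acceptance_rate=accepted_post / max(proposals_post, 1),
            config=config,
            warnings=warn,
        )

    def _labels(self) -> list[str]:
        return [s.label for s in self.sources]

    @staticmethod
    def _diagnostics(chain_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_chains, n_draws, N = chain_draws.shape
        if n_chains < 2 or n_draws < 4:
            return np.full(N, np.nan), np.full(N, np.nan)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(chain_draws)
            rhat = az.rhat(ds)["x"].values.astype(float)
            ess = az.ess(ds)["x"].values.astype(float)
        return rhat, ess


def sample_posterior(
    sources: Sequence[SourceLayer],
    obs: MixtureObservation,
    config: MCMCConfig | None = None,
) -> MixingResults:
    """Functional entry point: fit the mixing model and return the posterior."""
    return IsotopeMixingModel(obs, sources).fit(config)


def summarize_posterior(posterior: MixingResults) -> pd.DataFrame:
    """Posterior summary table (layer, mean, 2.5 %, 97.5 %, rhat, ess)."""
    return posterior.summary()
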