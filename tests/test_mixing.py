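import math

import numpy as np
import pytest
from scipy import stats

from isopart.mixing import (
    DEFAULT_LAYER_BOUNDS,
    IsotopeMixingModel,
    MCMCConfig,
    MixtureObservation,
    SourceLayer,
    build_sources,
    log_likelihood,
    predict_mixture,
    sample_posterior,
    summarize_posterior,
)
from .conftest import make_soil


class TestBuildSources:
    def test_single_sample_layer(self):
        layers = build_sources([make_soil(4, -4.0)], [(0, 5)])
        (layer,) = layers
        assert layer.mean_d18O == -4.0 and layer.sd_d18O == 0.0 and layer.n == 1

    def test_two_sample_layer_mean_and_sd(self):
        layers = build_sources(
            [make_soil(10, -6.0), make_soil(20, -8.0)], [(5, 20)]
        )
        (layer,) = layers
        assert layer.mean_d18O == pytest.approx(-7.0)
        assert layer.sd_d18O == pytest.approx(math.sqrt(2.0))
        assert layer.n == 2

    def test_campaign_depths_fill_default_layers(self):
        depths = (5, 10, 20, 40, 60, 80, 100)
        soils = [make_soil(d, -4.0 - 0.07 * d) for d in depths]
        layers = build_sources(soils, DEFAULT_LAYER_BOUNDS)
        assert [l.n for l in layers] == [1, 2, 2, 2]
        # boundary samples cap the layer above: 20 cm ends the 5-20 layer
        assert layers[1].mean_d18O == pytest.approx(np.mean([-4.7, -5.4]))

    def test_empty_layer_is_named_in_error(self):
        with pytest.raises(ValueError, match="0-5cm"):
            build_sources([make_soil(50, -8.0)], [(0, 5), (5, 60)])


class TestPredictMixture:
    def test_unit_vector_returns_that_source(self, well_separated_sources):
        d18O, dD = predict_mixture((1, 0, 0, 0), well_separated_sources)
        assert d18O == well_separated_sources[0].mean_d18O
        assert dD == well_separated_sources[0].mean_dD

    def test_uniform_mixture_averages(self, well_separated_sources):
        d18O, _ = predict_mixture((0.25,) * 4, well_separated_sources)
        assert d18O == pytest.approx(-8.0)

    def test_permutation_symmetry(self, well_separated_sources):
        f = (0.4, 0.3, 0.2, 0.1)
        perm = [2, 0, 3, 1]
        direct = predict_mixture(f, well_separated_sources)
        permuted = predict_mixture(
            tuple(f[i] for i in perm), [well_separated_sources[i] for i in perm]
        )
        assert direct == pytest.approx(permuted)

    def test_off_simplex_rejected(self, well_separated_sources):
        with pytest.raises(ValueError):
            predict_mixture((0.5, 0.5, 0.5, -0.5), well_separated_sources)
        with pytest.raises(ValueError):
            predict_mixture((0.3, 0.3, 0.3, 0.3), well_separated_sources)


class TestLogLikelihood:
    def test_exact_match_leaves_only_normalisation(self, well_separated_sources):
        f = (0.25,) * 4
        d18O, dD = predict_mixture(f, well_separated_sources)
        obs = MixtureObservation(d18O, dD)
        expected = -0.5 * math.log(2 * math.pi * obs.sigma_d18O**2) - 0.5 * math.log(
            2 * math.pi * obs.sigma_dD**2
        )
        got = log_likelihood(f, well_separated_sources, obs, "measurement_only")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_one_sigma_shift_costs_half(self, well_separated_sources):
        f = (0.25,) * 4
        d18O, dD = predict_mixture(f, well_separated_sources)
        obs0 = MixtureObservation(d18O, dD)
        obs1 = MixtureObservation(d18O + obs0.sigma_d18O, dD)
        delta = log_likelihood(f, well_separated_sources, obs1, "measurement_only") - \
            log_likelihood(f, well_separated_sources, obs0, "measurement_only")
        assert delta == pytest.approx(-0.5, abs=1e-12)

    @pytest.mark.parametrize("mode", ["measurement_only", "siar_propagated"])
    def test_against_direct_gaussian_transcription(self, well_separated_sources, mode):
        rng = np.random.default_rng(42)
        means = np.array([[s.mean_d18O, s.mean_dD] for s in well_separated_sources])
        sds = np.array([[s.sd_d18O, s.sd_dD] for s in well_separated_sources])
        for _ in range(100):
            f = rng.dirichlet(np.ones(4))
            obs = MixtureObservation(
                float(rng.uniform(-15, 0)), float(rng.uniform(-120, -10))
            )
            # independent transcription of the Gaussian density
            pred = f @ means
            var = np.array([obs.sigma_d18O**2, obs.sigma_dD**2])
            if mode == "siar_propagated":
                var = var + (f**2) @ (sds**2)
            expected = sum(
                stats.norm.logpdf(y, loc=m, scale=math.sqrt(v))
                for y, m, v in zip([obs.d18O, obs.dD], pred, var)
            )
            got = log_likelihood(f, well_separated_sources, obs, mode)
            assert got == pytest.approx(expected, abs=1e-10)


class TestPosteriorSampling:
    def test_identical_sources_recover_uniform_fractions(self, fast_mcmc):
        src = [
            SourceLayer(f"L{i}", 20 * i, 20 * (i + 1), -7.0, 0.2, -46.5, 1.0, 3)
            for i in range(4)
        ]
        res = sample_posterior(src, MixtureObservation(-7.0, -46.5), fast_mcmc)
        assert np.allclose(res.mean, 0.25, atol=0.02)

    def test_well_separated_recovery(self, well_separated_sources, fast_mcmc):
        f_true = np.array([0.6, 0.25, 0.10, 0.05])
        d18O, dD = predict_mixture(f_true, well_separated_sources)
        res = sample_posterior(
            well_separated_sources, MixtureObservation(d18O, dD), fast_mcmc
        )
        assert np.all(np.abs(res.mean - f_true) < 0.10)

    def test_posterior_predictive_covers_observation(
        self, well_separated_sources, fast_mcmc
    ):
        f_true = np.array([0.5, 0.3, 0.15, 0.05])
        d18O, dD = predict_mixture(f_true, well_separated_sources)
        obs = MixtureObservation(d18O, dD)
        res = sample_posterior(well_separated_sources, obs, fast_mcmc)
        pred = predict_mixture(res.mean / res.mean.sum(), well_separated_sources)
        sds = np.array([[s.sd_d18O, s.sd_dD] for s in well_separated_sources])
        var = np.array([obs.sigma_d18O**2, obs.sigma_dD**2]) + (res.mean**2) @ (sds**2)
        assert abs(pred[0] - obs.d18O) < 2 * math.sqrt(var[0])
        assert abs(pred[1] - obs.dD) < 2 * math.sqrt(var[1])

    def test_draws_live_on_simplex(self, well_separated_sources, fast_mcmc):
        d18O, dD = predict_mixture((0.4, 0.3, 0.2, 0.1), well_separated_sources)
        res = sample_posterior(
            well_separated_sources, MixtureObservation(d18O, dD), fast_mcmc
        )
        assert np.all(res.draws >= 0)
        assert np.allclose(res.draws.sum(axis=1), 1.0, atol=1e-12)

    def test_flat_likelihood_recovers_dirichlet_prior(self, well_separated_sources, fast_mcmc):
        # enormous measurement sigmas flatten the likelihood; the posterior
        # must then match the Dirichlet(1) prior: mean 1/4, var 3/80
        obs = MixtureObservation(-8.0, -60.0, sigma_d18O=1e6, sigma_dD=1e6)
        res = sample_posterior(well_separated_sources, obs, fast_mcmc)
        assert np.allclose(res.mean, 0.25, atol=0.02)
        assert np.allclose(res.draws.var(axis=0), 3.0 / 80.0, atol=0.012)

    def test_determinism(self, well_separated_sources, fast_mcmc):
        d18O, dD = predict_mixture((0.4, 0.3, 0.2, 0.1), well_separated_sources)
        obs = MixtureObservation(d18O, dD)
        r1 = sample_posterior(well_separated_sources, obs, fast_mcmc)
        r2 = sample_posterior(well_separated_sources, obs, fast_mcmc)
        assert np.array_equal(r1.draws, r2.draws)

    def test_model_validates_inputs(self, well_separated_sources):
        obs = MixtureObservation(-8.0, -60.0)
        with pytest.raises(ValueError):
            IsotopeMixingModel(obs, well_separated_sources[:1])
        with pytest.raises(ValueError):
            MixtureObservation(-8.0, -60.0, sigma_d18O=0.0)
        with pytest.raises(ValueError):
            MCMCConfig(burn_in=100, n_iter=100)


class TestSummary:
    def test_summary_matches_draw_moments(self, well_separated_sources, fast_mcmc):
        d18O, dD = predict_mixture((0.4, 0.3, 0.2, 0.1), well_separated_sources)
        res = sample_posterior(
            well_separated_sources, MixtureObservation(d18O, dD), fast_mcmc
        )
        table = summarize_posterior(res)
        assert table["mean"].sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(table["mean"], res.draws.mean(axis=0))
        # intervals against an independent sort-based quantile rule
        for i in range(4):
            col = np.sort(res.draws[:, i])
            lo = col[int(np.floor(0.025 * (len(col) - 1)))]
            hi = col[int(np.ceil(0.975 * (len(col) - 1)))]
            assert table["lo95"][i] == pytest.approx(lo, abs=5e-3)
            assert table["hi95"][i] == pytest.approx(hi, abs=5e-3)
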