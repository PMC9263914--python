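import numpy as np
import pytest

from isopart.isotopes import SampleKind, fit_meteoric_line
from isopart.mixing import build_sources
from isopart.rld import fit_saturating
from isopart.synthetic import (
    SOIL_SAMPLING_DEPTHS,
    SyntheticConfig,
    generate_dataset,
    generate_precipitation,
    generate_rld_profiles,
    generate_soil_profiles,
    generate_stem_samples,
    generate_uptake_points,
    generate_weather,
)

SMALL = dict(n_dates=2, treatments=("P1-N120", "P2-N240"))


class TestSoilProfiles:
    def test_noiseless_profiles_match_configured_curve(self):
        cfg = SyntheticConfig(seed=1, **SMALL).noiseless()
        for s in generate_soil_profiles(cfg):
            assert s.d18O_permil == pytest.approx(cfg.soil_d18O(s.depth_cm))
            assert s.dD_permil == pytest.approx(cfg.soil_dD(s.d18O_permil, s.depth_cm))

    def test_deep_water_more_depleted_than_shallow(self):
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed, **SMALL)
            soils = generate_soil_profiles(cfg)
            at = lambda d: np.mean([s.d18O_permil for s in soils if s.depth_cm == d])
            assert at(100.0) < at(5.0)

    def test_same_seed_same_output(self):
        cfg = SyntheticConfig(seed=9, **SMALL)
        assert generate_soil_profiles(cfg) == generate_soil_profiles(cfg)

    def test_campaign_depths_present_per_group(self):
        cfg = SyntheticConfig(seed=2, **SMALL)
        soils = generate_soil_profiles(cfg)
        groups = {(s.date, s.treatment) for s in soils}
        assert len(groups) == 4
        for g in groups:
            depths = sorted(s.depth_cm for s in soils if (s.date, s.treatment) == g)
            assert tuple(depths) == SOIL_SAMPLING_DEPTHS


class TestStemSamples:
    def test_noiseless_unit_fraction_returns_layer_mean(self):
        cfg = SyntheticConfig(seed=4, **SMALL).noiseless()
        truths = {
            (d.isoformat(), t): (1.0, 0.0, 0.0, 0.0)
            for d in cfg.dates()
            for t in cfg.treatments
        }
        cfg = SyntheticConfig(seed=4, true_fractions=truths, **SMALL).noiseless()
        soils = generate_soil_profiles(cfg)
        for stem in generate_stem_samples(cfg, soils):
            group = [
                s for s in soils if (s.date, s.treatment) == (stem.date, stem.treatment)
            ]
            layer1 = build_sources(group, cfg.layer_bounds)[0]
            assert stem.d18O_permil == pytest.approx(layer1.mean_d18O)
            assert stem.dD_permil == pytest.approx(layer1.mean_dD)

    def test_noiseless_stem_in_convex_hull_of_layer_means(self):
        cfg = SyntheticConfig(seed=5, **SMALL).noiseless()
        soils = generate_soil_profiles(cfg)
        for stem in generate_stem_samples(cfg, soils):
            group = [
                s for s in soils if (s.date, s.treatment) == (stem.date, stem.treatment)
            ]
            means = [l.mean_d18O for l in build_sources(group, cfg.layer_bounds)]
            assert min(means) - 1e-9 <= stem.d18O_permil <= max(means) + 1e-9


class TestRootsAndUptake:
    def test_flat_decay_without_jitter_gives_uniform_bins(self):
        cfg = SyntheticConfig(seed=1, rld_decay_per_cm=0.0, rld_jitter_cv=0.0, **SMALL)
        rld = generate_rld_profiles(cfg)
        one = rld[(rld.date == rld.date.iloc[0]) & (rld.treatment == rld.treatment.iloc[0])]
        frac = one.root_length_cm / one.root_length_cm.sum()
        assert np.allclose(frac, 0.1, atol=1e-12)

    def test_monotone_decline_without_jitter(self):
        cfg = SyntheticConfig(seed=1, rld_jitter_cv=0.0, **SMALL)
        rld = generate_rld_profiles(cfg)
        one = rld[(rld.date == rld.date.iloc[0]) & (rld.treatment == rld.treatment.iloc[0])]
        lengths = one.sort_values("bin_top_cm").root_length_cm.to_numpy()
        assert np.all(np.diff(lengths) <= 0)

    def test_noiseless_uptake_points_refit_to_truth(self):
        cfg = SyntheticConfig(seed=1, **SMALL).noiseless()
        fit = fit_saturating(generate_uptake_points(cfg))
        assert fit.k == pytest.approx(cfg.uptake_k, rel=1e-3)
        assert fit.A == pytest.approx(cfg.uptake_A, rel=1e-3)


class TestPrecipitationAndWeather:
    def test_scatter_free_events_sit_on_the_line(self):
        cfg = SyntheticConfig(seed=6, **SMALL).noiseless()
        events = generate_precipitation(cfg)
        line = fit_meteoric_line([(s.d18O_permil, s.dD_permil) for s in events])
        assert line.slope == pytest.approx(cfg.lmwl_slope, abs=1e-9)
        assert line.intercept == pytest.approx(cfg.lmwl_intercept, abs=1e-9)

    def test_amount_range_straddles_filter_threshold(self):
        cfg = SyntheticConfig(seed=6, n_rain_events=40, **SMALL)
        amounts = [s.amount_mm for s in generate_precipitation(cfg)]
        assert min(amounts) <= 5.0 < max(amounts)

    def test_weather_within_ranges_and_physical(self):
        cfg = SyntheticConfig(seed=6, **SMALL)
        for day in generate_weather(cfg):
            assert cfg.T_range[0] <= day.T_mean <= cfg.T_range[1]
            assert cfg.Rn_range[0] <= day.Rn <= cfg.Rn_range[1]
            assert 0 <= day.ea <= day.es

    def test_determinism(self):
        cfg = SyntheticConfig(seed=8, **SMALL)
        assert generate_precipitation(cfg) == generate_precipitation(cfg)
        assert generate_weather(cfg) == generate_weather(cfg)


class TestFullDataset:
    def test_writes_all_files(self, tmp_path):
        cfg = SyntheticConfig(seed=3, **SMALL)
        generate_dataset(cfg, tmp_path)
        for name in ("water_samples.csv", "rld.csv", "weather.csv",
                     "uptake_points.csv", "truth.json"):
            assert (tmp_path / name).exists()

    def test_truth_records_every_group(self):
        cfg = SyntheticConfig(seed=3, **SMALL)
        ds = generate_dataset(cfg)
        assert len(ds.truth["true_fractions"]) == 4
        for f in ds.truth["true_fractions"].values():
            assert sum(f) == pytest.approx(1.0, abs=1e-9)

    def test_substreams_are_independent(self):
        # changing rain count must not perturb the soil substream
        a = SyntheticConfig(seed=3, **SMALL)
        b = SyntheticConfig(seed=3, n_rain_events=40, **SMALL)
        assert generate_soil_profiles(a) == generate_soil_profiles(b)
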