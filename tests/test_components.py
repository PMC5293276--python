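"""Generative model: latent components, Poisson counts, presets."""

import dataclasses

import numpy as np
import pytest

import areavar as av


class TestDrawComponents:
    def test_zero_interaction_sd_gives_shared_trend(self, small_geo):
        c = av.draw_components(small_geo, 6, (0.2, 0.1, 0.1, 0.0),
                               "linear_up", seed=1)
        assert np.all(c.delta == 0.0)

    def test_inverted_v_peaks_at_requested_interior_year(self, small_geo):
        # T=12 window: peak maps to year index 7 (2009 in a 2002-2013 window)
        c = av.draw_components(small_geo, 12, (0.1, 0.1, 0.1, 0.1),
                               "inverted_V", seed=2)
        assert np.argmax(c.gamma) == 7
        assert 0 < np.argmax(c.gamma) < 11

    def test_sample_sd_matches_requested_sigma(self):
        # chi-square bound on the SD of 1000 iid normals (~99% confidence)
        geo = av.make_nested_geography(4, 250, seed=3, with_geometry=False)
        c = av.draw_components(geo, 4, (1.0, 0.1, 0.1, 0.1), "linear_up", seed=4)
        assert 0.93 <= c.u.std() <= 1.07

    def test_components_are_centered(self, small_geo):
        c = av.draw_components(small_geo, 8, (0.3, 0.2, 0.1, 0.15),
                               "inverted_V", seed=5,
                               interaction_mix=0.5, interaction_trend="up")
        assert abs(c.u.mean()) < 1e-12
        assert abs(c.v.mean()) < 1e-12
        assert abs(c.gamma.mean()) < 1e-12
        assert abs(c.delta.mean()) < 1e-12

    def test_modulated_interaction_is_centered_in_both_margins(self, small_geo):
        c = av.draw_components(small_geo, 8, (0.0, 0.2, 0.0, 0.15),
                               "linear_up", seed=6,
                               interaction_mix=1.0, interaction_trend="down")
        assert np.allclose(c.delta.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(c.delta.mean(axis=1), 0.0, atol=1e-12)

    def test_rw1_shape_draws_a_random_walk(self, small_geo):
        c = av.draw_components(small_geo, 10, (0.1, 0.1, 0.2, 0.1), "rw1", seed=7)
        # realized increment precision is recorded
        assert c.tau_gamma == pytest.approx(1.0 / np.var(np.diff(c.gamma)))

    def test_unknown_trend_shape_raises(self, small_geo):
        with pytest.raises(ValueError):
            av.draw_components(small_geo, 6, (0.1,) * 4, "quadratic", seed=0)

    def test_determinism(self, small_geo):
        a = av.draw_components(small_geo, 6, (0.2, 0.1, 0.1, 0.1), "rw1", seed=9)
        b = av.draw_components(small_geo, 6, (0.2, 0.1, 0.1, 0.1), "rw1", seed=9)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.delta, b.delta)


class TestSimulateCounts:
    def test_zero_population_gives_zero_counts(self, small_geo):
        pop = av.simulate_population(small_geo, T=3, seed=1)
        pop = dataclasses.replace(pop, person_years=np.zeros_like(pop.person_years))
        comps = av.draw_components(small_geo, 3, (0.1,) * 4, "linear_up", seed=2)
        rates = np.full(len(pop.strata), 1e-3)
        panel = av.simulate_counts(small_geo, pop, comps, 0.0, rates, seed=3)
        assert np.all(panel.o == 0) and np.all(panel.e == 0)

    def test_poisson_mean_structure(self):
        # 10,000 replicate cells with e = 5: mean within 3 SE of 5
        geo = av.make_nested_geography(1, 1, seed=0, with_geometry=False)
        pop = av.StratifiedPopulation(
            area_ids=geo.area_ids,
            years=tuple(range(2002, 2002 + 10_000)),
            strata=(("20-24", "F"),),
            person_years=np.full((1, 10_000, 1), 5_000.0),
        )
        comps = av.ModelComponents(
            beta=0.0, u=np.zeros(1), v=np.zeros(1), gamma=np.zeros(10_000),
            delta=np.zeros((1, 10_000)), tau_u=np.inf, tau_v=np.inf,
            tau_gamma=np.inf, tau_delta=np.inf,
        )
        panel = av.simulate_counts(geo, pop, comps, 0.0, np.array([1e-3]), seed=4)
        assert np.all(panel.e == 5.0)
        se = np.sqrt(5.0 / 10_000)
        assert abs(panel.o.mean() - 5.0) < 3 * se

    def test_observed_equals_stratified_sum(self, small_panel):
        assert np.array_equal(small_panel.o, small_panel.o_strat.sum(axis=2))

    def test_determinism(self, small_geo, small_pop):
        comps = av.draw_components(small_geo, 6, (0.1,) * 4, "linear_up", seed=5)
        rates = av.calibrate_stratum_rates(small_pop, 8.0)
        a = av.simulate_counts(small_geo, small_pop, comps, 0.0, rates, seed=6)
        b = av.simulate_counts(small_geo, small_pop, comps, 0.0, rates, seed=6)
        assert np.array_equal(a.o, b.o)


class TestScenarioConfig:
    def test_validation(self):
        good = dict(J=2, areas_per_region=3, T=4, baseline_rate=5.0,
                    trend_shape="linear_up",
                    component_sds=(0.1, 0.1, 0.1, 0.1), seed=0)
        av.ScenarioConfig(**good)
        for bad in ({"T": 1}, {"baseline_rate": 0.0},
                    {"component_sds": (-0.1, 0.1, 0.1, 0.1)},
                    {"trend_shape": "cubic"}, {"interaction_mix": 1.5}):
            with pytest.raises(ValueError):
                av.ScenarioConfig(**{**good, **bad})

    def test_explicit_config_pipeline_is_deterministic(self):
        cfg = av.ScenarioConfig(
            J=3, areas_per_region=4, T=5, baseline_rate=8.0,
            trend_shape="inverted_V", component_sds=(0.2, 0.1, 0.05, 0.05),
            seed=21,
        )
        a = av.simulate_scenario(cfg)
        b = av.simulate_scenario(cfg)
        assert np.array_equal(a[2].o, b[2].o)
        # calibrated level makes the year-one crude rate match the baseline
        rate1 = a[2].o[:, 0].sum() / a[1].totals[:, 0].sum() * 1e4
        assert abs(rate1 - 8.0) / 8.0 < 0.15


class TestPresets:
    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError):
            av.preset_scenario("asthma", seed=0)

    def test_generative_interaction_fractions_bracket_the_archetypes(self):
        # at the study's own dimensions, averaged over a few realizations
        def mean_frac(name):
            vals = []
            for seed in (1, 2, 3):
                geo, _, _, comps = av.preset_scenario(name, seed,
                                                      with_geometry=False)
                vals.append(
                    av.fractions_from_components(comps, geo).fractions[
                        "interaction"
                    ]
                )
            return float(np.mean(vals))

        assert mean_frac("PCI_like") >= 0.15
        assert mean_frac("COPD_like") <= 0.05

    def test_generative_scenario_separation(self):
        # interaction: PCI > CCC > COPD; AC fraction largest for COPD
        fr = {}
        for name in av.PRESETS:
            geo, _, _, comps = av.preset_scenario(
                name, 2, J=8, areas_per_region=10, T=12, with_geometry=False
            )
            fr[name] = av.fractions_from_components(comps, geo).fractions
        assert (fr["PCI_like"]["interaction"] > fr["CCC_like"]["interaction"]
                > fr["COPD_like"]["interaction"])
        assert fr["COPD_like"]["AC"] > fr["PCI_like"]["AC"]
        assert fr["COPD_like"]["AC"] > fr["CCC_like"]["AC"]

    def test_copd_year_one_crude_rate_near_baseline(self):
        geo, pop, panel, _ = av.preset_scenario(
            "COPD_like", 3, J=6, areas_per_region=8, T=12, with_geometry=False
        )
        rate1 = panel.o[:, 0].sum() / pop.totals[:, 0].sum() * 1e4
        assert abs(rate1 - 21.0) / 21.0 < 0.15

    def test_preset_determinism(self):
        a = av.preset_scenario("CCC_like", 5, J=4, areas_per_region=5, T=6,
                               with_geometry=False)
        b = av.preset_scenario("CCC_like", 5, J=4, areas_per_region=5, T=6,
                               with_geometry=False)
        assert np.array_equal(a[2].o, b[2].o)
        assert np.array_equal(a[3].delta, b[3].delta)

    def test_default_dimensions_match_study(self):
        geo, pop, panel, comps = av.preset_scenario(
            "CCC_like", 4, with_geometry=False
        )
        assert geo.n_areas == 203 and geo.n_regions == 17
        assert panel.n_years == 12 and panel.years[0] == 2002
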