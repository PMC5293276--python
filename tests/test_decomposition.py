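"""Variance partitioning, yearly variance, sensitivity mechanics."""

import dataclasses
import warnings

import numpy as np
import pytest

import areavar as av
from areavar.decomposition import expand_to_grid


def _comps(geo, T, u=None, v=None, gamma=None, delta=None, beta=0.0):
    I, J = geo.n_areas, geo.n_regions
    return av.ModelComponents(
        beta=beta,
        u=np.zeros(I) if u is None else u,
        v=np.zeros(J) if v is None else v,
        gamma=np.zeros(T) if gamma is None else gamma,
        delta=np.zeros((J, T)) if delta is None else delta,
        tau_u=1.0, tau_v=1.0, tau_gamma=1.0, tau_delta=1.0,
    )


class TestExpandToGrid:
    def test_surfaces_reconstruct_linear_predictor(self, small_geo):
        T = 5
        rng = np.random.default_rng(0)
        comps = _comps(
            small_geo, T,
            u=rng.normal(size=small_geo.n_areas),
            v=rng.normal(size=small_geo.n_regions),
            gamma=rng.normal(size=T),
            delta=rng.normal(size=(small_geo.n_regions, T)),
            beta=0.7,
        )
        surf = expand_to_grid(comps.u, comps.v, comps.gamma, comps.delta,
                              small_geo, T)
        total = comps.beta + sum(surf.values())
        eta = comps.linear_predictor(small_geo.region_index)
        assert np.allclose(total, eta, atol=1e-12)

    def test_single_region_has_constant_zero_variance_region_surface(self):
        geo = av.make_nested_geography(1, 4, seed=1, with_geometry=False)
        surf = expand_to_grid(
            np.zeros(4), np.array([0.0]), np.zeros(3), np.zeros((1, 3)), geo, 3
        )
        assert np.var(surf["AC"]) == 0.0

    def test_hand_computed_toy_broadcast(self):
        geo = av.Geography(
            region_ids=("A", "B"),
            area_ids=("a1", "a2", "b1"),
            parent={"a1": "A", "a2": "A", "b1": "B"},
        )
        u = np.array([0.1, -0.1, 0.0])
        v = np.array([0.5, -0.5])
        gamma = np.array([1.0, -1.0])
        delta = np.array([[0.2, -0.2], [-0.3, 0.3]])
        surf = expand_to_grid(u, v, gamma, delta, geo, 2)
        assert np.allclose(surf["AC"], [[0.5, 0.5], [0.5, 0.5], [-0.5, -0.5]])
        assert np.allclose(surf["interaction"],
                           [[0.2, -0.2], [0.2, -0.2], [-0.3, 0.3]])
        assert np.allclose(surf["temporal"], [[1, -1], [1, -1], [1, -1]])


class TestFractions:
    def test_single_active_component(self, small_geo):
        comps = _comps(small_geo, 4, u=np.array([1.0, -1.0] * 6))
        dec = av.fractions_from_components(comps, small_geo)
        assert dec.fractions["HA"] == pytest.approx(1.0)
        assert dec.fractions["AC"] == 0.0

    def test_fractions_sum_to_one_and_shift_invariant(self, small_fit):
        dec = av.fractions_of_variance(small_fit)
        assert sum(dec.fractions.values()) == pytest.approx(1.0, abs=1e-10)
        shifted = dataclasses.replace(small_fit, beta=small_fit.beta + 3.0)
        dec2 = av.fractions_of_variance(shifted)
        for k in dec.fractions:
            assert dec2.fractions[k] == pytest.approx(dec.fractions[k])

    def test_equal_variance_components_approach_quarter_shares(self):
        # independent equal-variance components on a large balanced grid
        geo = av.make_nested_geography(30, 20, seed=2, with_geometry=False)
        T = 40
        rng = np.random.default_rng(3)
        comps = _comps(
            geo, T,
            u=rng.normal(size=600), v=rng.normal(size=30),
            gamma=rng.normal(size=T), delta=rng.normal(size=(30, T)),
        )
        dec = av.fractions_from_components(comps, geo)
        for frac in dec.fractions.values():
            assert frac == pytest.approx(0.25, abs=0.07)

    def test_cell_equals_unit_weighting_on_balanced_design(self, small_geo):
        rng = np.random.default_rng(4)
        comps = _comps(
            small_geo, 4,
            u=rng.normal(size=small_geo.n_areas),
            v=rng.normal(size=small_geo.n_regions),
            gamma=rng.normal(size=4),
            delta=rng.normal(size=(small_geo.n_regions, 4)),
        )
        cell = av.fractions_from_components(comps, small_geo, weighting="cell")
        unit = av.fractions_from_components(comps, small_geo, weighting="unit")
        for k in cell.fractions:
            assert cell.fractions[k] == pytest.approx(unit.fractions[k])

    def test_zero_total_variance_flagged(self, small_geo):
        comps = _comps(small_geo, 3)
        with pytest.raises(ValueError):
            av.fractions_from_components(comps, small_geo)


class TestYearlyVariance:
    def test_identical_risks_give_zero(self, small_geo):
        comps = _comps(small_geo, 3, gamma=np.array([0.2, -0.1, -0.1]))
        # no spatial structure: variance across areas is zero in every year
        surf = expand_to_grid(comps.u, comps.v, comps.gamma, comps.delta,
                              small_geo, 3)
        total = comps.beta + sum(surf.values())
        assert np.allclose(total.var(axis=0), 0.0)

    def test_one_value_per_year_from_fit(self, small_fit):
        yv = av.yearly_risk_variance(small_fit)
        assert len(yv) == len(small_fit.years)
        assert (yv >= 0).all()
        rr = av.yearly_risk_variance(small_fit, basis="rr")
        assert "rr" in rr.name


class TestSingularRegionFlagger:
    def test_scores_invariant_to_region_relabeling(self, small_fit):
        scores = av.singular_region_flagger(small_fit)
        assert set(scores["region_id"]) == set(small_fit.geo.region_ids)
        assert (scores["score"].values[:-1] >= scores["score"].values[1:]).all()

    def test_null_interaction_gives_uniform_low_scores(self, null_summary):
        scores = av.singular_region_flagger(null_summary)
        assert scores["score"].max() < 1.0  # below one posterior SD


@pytest.fixture(scope="module")
def null_summary():
    geo = av.make_nested_geography(4, 4, seed=9, with_geometry=False)
    rng = np.random.default_rng(10)
    e = np.full((16, 5), 150.0)
    panel = av.CountsPanel(
        area_ids=geo.area_ids, years=tuple(range(2002, 2007)),
        o=rng.poisson(e), e=e, person_years=e * 100,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", av.ConvergenceWarning)
        return av.fit(panel, geo, chains=2, warmup=300, draws=200, seed=11,
                      max_leapfrog=48)


class TestSensitivityRefit:
    def test_empty_exclusion_is_a_no_op(self, small_geo, small_panel, small_fit):
        res = av.sensitivity_refit(
            small_panel, small_geo, exclude_regions=[],
            full_summary=small_fit,
            chains=2, warmup=300, draws=200, seed=15, max_leapfrog=48,
        )
        for k in res.full.fractions:
            assert res.reduced.fractions[k] == pytest.approx(
                res.full.fractions[k]
            )

    def test_exclusion_below_two_regions_raises(self, small_geo, small_panel):
        with pytest.raises(ValueError):
            av.sensitivity_refit(
                small_panel, small_geo,
                exclude_regions=list(small_geo.region_ids[:2]),
            )

    def test_unknown_region_raises(self, small_geo, small_panel):
        with pytest.raises(ValueError):
            av.sensitivity_refit(small_panel, small_geo,
                                 exclude_regions=["Atlantis"])
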