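"""Classical variation statistics against brute-force oracles."""

import numpy as np
import pytest

import areavar as av
from areavar.descriptive import DataError


# ---------------------------------------------------------------- oracles
def oracle_direct_rate(c, n, w):
    total, wsum = 0.0, 0.0
    for ci, ni, wi in zip(c, n, w):
        r = ci / ni if ni > 0 else 0.0
        total += wi * r
        wsum += wi
    return total / wsum * 1e4


def oracle_expected(o_strat, py_strat):
    I, T, S = o_strat.shape
    e = np.zeros((I, T))
    for s in range(S):
        num = o_strat[:, :, s].sum()
        den = py_strat[:, :, s].sum()
        rate = num / den if den > 0 else 0.0
        e += rate * py_strat[:, :, s]
    return e


def oracle_scv(o, e):
    k = len(o)
    total = 0.0
    for oi, ei in zip(o, e):
        total += (oi - ei) ** 2 / ei**2 - 1.0 / ei
    return total / k


def oracle_eq(rates):
    lo, hi = np.percentile(rates, [5, 95], method="hazen")
    keep = [r for r in rates if lo <= r <= hi]
    return max(keep) / min(keep)


# ------------------------------------------------------- worked examples
class TestDirectStandardizedRate:
    def test_single_stratum_equals_crude_rate(self):
        assert av.direct_standardized_rate([10], [10_000], [7.0]) == 10.0

    def test_equal_weights_average_rates(self):
        r = av.direct_standardized_rate([5, 15], [10_000, 10_000], [1, 1])
        assert r == pytest.approx(10.0)

    def test_hand_computed_example(self):
        r = av.direct_standardized_rate([2, 9], [4_000, 6_000], [500, 500])
        assert r == pytest.approx(10.0)

    def test_zero_person_year_stratum_warns_and_contributes_zero(self):
        with pytest.warns(UserWarning):
            r = av.direct_standardized_rate([5, 0], [10_000, 0], [1, 1])
        assert r == pytest.approx(2.5)

    def test_mismatched_strata_raise(self):
        with pytest.raises(DataError):
            av.direct_standardized_rate([1, 2], [10.0], [1, 1])


class TestExpectedCounts:
    def test_equal_crude_rates_reproduce_observed(self):
        o = np.array([[10.0], [30.0]])[:, :, None]
        n = np.array([[1_000.0], [3_000.0]])[:, :, None]
        e = av.expected_counts(o, n)
        assert np.allclose(e, [[10.0], [30.0]])

    def test_pooled_rate_example(self):
        o = np.array([[0.0], [40.0]])[:, :, None]
        n = np.array([[1_000.0], [3_000.0]])[:, :, None]
        e = av.expected_counts(o, n)
        assert np.allclose(e, [[10.0], [30.0]])

    def test_conservation(self, small_panel, small_pop):
        e = av.expected_counts(small_panel.o_strat, small_pop.person_years)
        assert abs(e.sum() - small_panel.o.sum()) < 1e-8 * small_panel.o.sum()

    def test_all_zero_person_years_raise(self):
        with pytest.raises(DataError):
            av.expected_counts(np.ones((2, 1, 1)), np.zeros((2, 1, 1)))


class TestShr:
    def test_ratio_and_zero_exposure_flag(self):
        out = av.shr(np.array([10.0, 12.0, 0.0]), np.array([10.0, 8.0, 0.0]))
        assert out[0] == 1.0 and out[1] == 1.5
        assert np.isnan(out[2])


class TestExtremalQuotient:
    def test_no_spread(self):
        assert av.extremal_quotient_5_95(np.full(10, 7.7)) == 1.0

    def test_percentile_trim_on_1_to_100(self):
        eq = av.extremal_quotient_5_95(np.arange(1.0, 101.0))
        assert eq == pytest.approx(95.0 / 6.0)

    def test_zero_minimum_flags_infinite(self):
        assert np.isinf(av.extremal_quotient_5_95(np.array([0.0, 5.0, 10.0])))

    def test_too_few_areas_raise(self):
        with pytest.raises(DataError):
            av.extremal_quotient_5_95(np.array([1.0]))

    def test_wider_trimming_never_increases_eq(self):
        # narrowing the surviving percentile band shrinks the survivor set,
        # so the max/min ratio is monotone in the trim width
        rng = np.random.default_rng(0)
        for _ in range(20):
            rates = rng.uniform(1.0, 10.0, size=30)
            raw = rates.max() / rates.min()
            eq_5_95 = av.extremal_quotient_5_95(rates)
            eq_10_90 = av.extremal_quotient_5_95(
                rates, lower_pct=10.0, upper_pct=90.0
            )
            assert eq_10_90 <= eq_5_95 + 1e-12 <= raw + 1e-12


class TestScv:
    def test_hand_computed_example(self):
        res = av.scv(np.array([80.0, 120.0]), np.array([100.0, 100.0]))
        assert res.value == pytest.approx(0.03)
        assert not res.truncated

    def test_negative_truncation_flag(self):
        res = av.scv(np.array([100.0, 100.0]), np.array([100.0, 100.0]))
        assert res.value == 0.0 and res.truncated

    def test_noise_term_vanishes_for_large_e(self):
        e = np.full(50, 1e9)
        res = av.scv(e.copy(), e)
        assert res.value == pytest.approx(0.0, abs=1e-8)

    def test_zero_expected_raises(self):
        with pytest.raises(DataError):
            av.scv(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


def test_oracle_equivalence_on_200_random_inputs():
    """SCV, EQ and standardization match brute-force oracles to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        k = int(rng.integers(2, 12))
        e = rng.uniform(0.5, 50.0, size=k)
        o = rng.poisson(e).astype(float)
        got = av.scv(o, e)
        assert got.value == pytest.approx(max(oracle_scv(o, e), 0.0), abs=1e-12)

        rates = rng.uniform(0.5, 20.0, size=int(rng.integers(3, 40)))
        assert av.extremal_quotient_5_95(rates) == pytest.approx(
            oracle_eq(rates), abs=1e-12
        )

        s = int(rng.integers(1, 6))
        c = rng.uniform(0, 30, size=s)
        n = rng.uniform(100, 10_000, size=s)
        w = rng.uniform(1, 100, size=s)
        assert av.direct_standardized_rate(c, n, w) == pytest.approx(
            oracle_direct_rate(c, n, w), abs=1e-12 * 1e4
        )

        I, T, S = (int(rng.integers(2, 5)) for _ in range(3))
        py = rng.uniform(10, 1_000, size=(I, T, S))
        os = rng.poisson(py * 0.01) + (1 if _ == 0 else 0)
        if os.sum() >= 1:
            got_e = av.expected_counts(os.astype(float), py)
            assert np.allclose(got_e, oracle_expected(os, py), atol=1e-10)


def test_scale_equivariance_of_standardized_rates():
    rng = np.random.default_rng(1)
    c = rng.uniform(0, 20, 4)
    n = rng.uniform(100, 1000, 4)
    w = rng.uniform(1, 10, 4)
    base = av.direct_standardized_rate(c, n, w)
    scaled = av.direct_standardized_rate(c, n, w * 37.5)
    assert scaled == pytest.approx(base, rel=1e-12)


class TestVariationTable:
    def test_full_battery_per_year(self, small_panel, small_pop):
        vt = av.variation_table(small_panel, small_pop)
        assert len(vt) == small_panel.n_years
        assert (vt["cases"] == small_panel.o.sum(axis=0)).all()
        assert (vt["eq5_95"] >= 1.0).all()
        assert (vt["scv"] >= 0.0).all()

    def test_single_area_panel_flags_spread_stats(self):
        geo = av.make_nested_geography(1, 1, seed=0, with_geometry=False)
        pop = av.simulate_population(geo, T=3, seed=1)
        comps = av.draw_components(geo, 3, (0.0,) * 4, "linear_up", seed=2)
        rates = av.calibrate_stratum_rates(pop, 10.0)
        panel = av.simulate_counts(geo, pop, comps, 0.0, rates, seed=3)
        vt = av.variation_table(panel, pop)
        assert vt["eq5_95"].isna().all() and vt["scv"].isna().all()
        assert vt["rate_per_10k"].notna().all()
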