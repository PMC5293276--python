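import numpy as np
import pytest

import areavar as av


@pytest.fixture(scope="session")
def small_geo():
    """3 regions x 4 areas, with geometry and adjacency."""
    return av.make_nested_geography(3, 4, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_geo):
    return av.simulate_population(small_geo, T=6, seed=12)


@pytest.fixture(scope="session")
def small_panel(small_geo, small_pop):
    comps = av.draw_components(
        small_geo, 6, (0.25, 0.15, 0.08, 0.08), "linear_up", seed=13
    )
    rates = av.calibrate_stratum_rates(small_pop, 10.0)
    return av.simulate_counts(small_geo, small_pop, comps, 0.0, rates, seed=14)


@pytest.fixture(scope="session")
def small_fit(small_geo, small_panel):
    """One shared short fit for export/decomposition plumbing tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", av.ConvergenceWarning)
        return av.fit(
            small_panel, small_geo, chains=2, warmup=300, draws=200, seed=15,
            max_leapfrog=48,
        )
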