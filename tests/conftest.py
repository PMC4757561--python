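import numpy as np
import pytest

import pcurvelab as pl


@pytest.fixture(scope="session")
def null_table():
    """Default synthetic growth table (true interest effect exactly zero)."""
    return pl.generate_growth_table(pl.default_spec("null-effect"), rng=42)


@pytest.fixture(scope="session")
def hacking_table(null_table):
    """Same table after null-outcome construction: the search substrate."""
    return pl.construct_null_outcome(null_table).table_with_null_outcome()


@pytest.fixture(scope="session")
def small_table():
    """Fast 60-row, 4-adjuster table for combinatorial/oracle tests."""
    spec = pl.SyntheticGrowthSpec(
        n_countries=60,
        n_adjusters=4,
        delta=(-1.0, 0.5, -0.25, 0.0),
    )
    return pl.generate_growth_table(spec, rng=7)


@pytest.fixture(scope="session")
def null_mc_pvalues():
    """10,000 p-values from the simulator under an exact null."""
    spec = pl.DGPSpec(gamma_max=0.0, beta_star=0.0, n_min=50, n_max=1000)
    return pl.monte_carlo_table(spec, 10_000, 11)["p_value"].to_numpy()
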