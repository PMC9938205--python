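import numpy as np
import pandas as pd
import pytest

from usprok.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A fast synthetic study: 2 cohorts over 20 ultra-small MAGs."""
    return SimulationConfig(
        seed=11,
        n_ultrasmall_mags=20,
        n_background_mags=5,
        n_cohorts=2,
        cohort_size_range=(3, 6),
        genes_per_mag_range=(40, 80),
        depth_range=(200_000, 1_000_000),
        library_size_range=(200_000, 1_000_000),
    )


@pytest.fixture
def toy_counts():
    """Two samples with totals 100 and 50."""
    return pd.DataFrame(
        {"s1": [60, 30, 10], "s2": [5, 25, 20]},
        index=["taxA", "taxB", "taxC"],
    )
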