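import numpy as np
import pandas as pd
import pytest

from scfptrial.io import AbundanceTable
from scfptrial.simulate import CohortConfig, generate_trial


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic trial used across modules (deterministic)."""
    cfg = CohortConfig(n_cats_per_arm=4, n_species=60, n_genera=15,
                       depth_range=(20_000, 60_000), n_butyrate_producers=8,
                       n_planted_trends=3, seed=42)
    return generate_trial(cfg)


@pytest.fixture()
def tiny_table():
    df = pd.DataFrame([[5, 0], [1, 3]], index=["s1", "s2"], columns=["taxA", "taxB"])
    return AbundanceTable(df, rank="species")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
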