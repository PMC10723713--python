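import numpy as np
import pytest

import fnclasso as fl


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_nested_dataset():
    """One small nested-scheme dataset with strong, well-separated signals."""
    scheme = fl.SimScheme(
        m=300, n=400, n0=4000, s_plus=20, delta=1.0,
        effect_low=0.2, effect_high=0.4, seed=3,
    )
    return fl.simulate_nested(scheme)


@pytest.fixture(scope="session")
def tiny_sumstats():
    """Hand-built summary statistics for IO and alignment tests."""
    import pandas as pd

    tab = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4"],
            "effect_allele": ["A", "C", "A", "C"],
            "other_allele": ["G", "T", "T", "G"],
            "effect": [0.5, -0.2, 0.1, 0.3],
            "se": [0.1, 0.1, 0.1, 0.1],
            "p": [1e-6, 0.02, 0.5, 0.9],
        }
    )
    return fl.SummaryStats(tab, n0=1000.0)
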