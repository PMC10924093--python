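import numpy as np
import pandas as pd
import pytest

from snpcca.simulate import CohortSpec, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cohort():
    """A small opposite-direction cohort shared across tests."""
    spec = CohortSpec(n_samples=600, n_snps=300, n_causal=5, effect_size=0.2, seed=7)
    g = simulate_genotypes(spec)
    sim = simulate_phenotypes(g, spec)
    return spec, g, sim


@pytest.fixture()
def toy_summary_frame():
    """Three hand-entered variants in the internal single-trait schema."""
    return pd.DataFrame(
        {
            "chrom": ["1", "2", "22"],
            "pos": [100, 200, 300],
            "rsid": ["rs1", "rs2", "rs3"],
            "ref": ["A", "C", "G"],
            "ea": ["G", "T", "A"],
            "af": [0.1, 0.25, 0.4],
            "beta": [0.05, -0.02, 0.0],
            "se": [0.01, 0.02, 0.03],
            "p": [1e-6, 0.3, 1.0],
            "n": [1000, 1000, 1000],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
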