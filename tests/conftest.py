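import warnings

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="corrupted purity")
        warnings.filterwarnings("ignore", message="no data peak")
        warnings.filterwarnings("ignore", message="expected peak below")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260201)


@pytest.fixture
def binomial_pool(rng):
    """Factory: (NV, DP) counts clustered at the theoretical peaks."""

    from peakqc.peaks import expected_vaf, multiplicity_set

    def make(n_a, n_b, purity, coverage=100, n=2000, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        legal = multiplicity_set(n_a, n_b)
        m = local.choice(legal, size=n)
        peaks = {mi: expected_vaf(mi, n_a, n_b, purity) for mi in legal}
        p = np.array([peaks[mi] for mi in m])
        dp = np.maximum(local.poisson(coverage, n), 1)
        nv = local.binomial(dp, p)
        return nv, dp

    return make


@pytest.fixture
def small_tumor():
    """One deterministic synthetic tumor shared across QC tests."""
    from peakqc.simulate import SimConfig, simulate_tumor

    return simulate_tumor(SimConfig(purity=0.8, coverage=90, seed=7, n_chromosomes=10))


@pytest.fixture
def tiny_segments():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "from": [1, 201, 1],
            "to": [200, 400, 500],
            "Major": [1, 2, 2],
            "minor": [1, 1, 0],
        }
    )
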