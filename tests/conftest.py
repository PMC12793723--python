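import numpy as np
import pytest

from triotmt import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """A 30-SNP x 40-trio structured quantitative cohort with 3 causal SNPs."""
    cfg = sim.SimConfig(n_trios=40, n_snps=30, n_causal=3, h2=0.4)
    return sim.simulate_cohort(cfg, seed=7)
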