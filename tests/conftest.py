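import logging

import pytest

import driverlens as dl

logging.getLogger("driverlens").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 30-sample, 300-gene cohort with planted ground truth."""
    cfg = dl.SyntheticConfig(n_samples=30, n_genes=300, n_tissues=20, seed=7)
    return dl.generate(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study cohort: 100 samples, 2,000 genes, fixed seed."""
    cfg = dl.SyntheticConfig(seed=20)
    return dl.generate(cfg)
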