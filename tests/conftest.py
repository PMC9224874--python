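import pytest

from tira.synth import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 234-sample cohort with 30 genes and one planted effect gene."""
    cfg = SynthConfig(n_genes=30, seed=11)
    g, db, clinical, truth = simulate_cohort(cfg)
    return cfg, g, db, clinical, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 60-sample cohort for I/O and pipeline plumbing tests."""
    cfg = SynthConfig(n_samples=60, n_cases=6, n_genes=8, n_null_snps=10, missing_rate=0.02, seed=5)
    g, db, clinical, truth = simulate_cohort(cfg)
    return cfg, g, db, clinical, truth
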