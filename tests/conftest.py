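import pytest

import reoscore as rs


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with planted pair structure (shared, read-only)."""
    cfg = rs.SimulationConfig(
        n_samples=150, n_genes=300, n_immune=40, n_weak=60, seed=7
    )
    return rs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ips():
    return rs.ips_signature()
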