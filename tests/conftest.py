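import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120913)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic admixed cohort reused across read-only tests."""
    from admixstrat.simulate import SimConfig, sample_ancestral_freqs, sample_cohort

    panel = sample_ancestral_freqs(60, 0.2, seed=11)
    cfg = SimConfig(
        n=600, m=60, fst=0.2, causal_effects={str(panel.snp_id[30]): 0.6},
        make_creatinine=True, seed=11,
    )
    cohort, truth = sample_cohort(cfg, panel)
    return panel, cfg, cohort, truth
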