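import pytest
from hypothesis import HealthCheck, settings

import methdex as mx

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a large promoter shift on 10 of 60 genes."""
    cfg = mx.SimulationConfig(
        n_cases=40,
        n_controls=40,
        n_genes=60,
        n_causal=10,
        effect_size=1.5,
        missing_rate=0.0,
        rng_seed=11,
    )
    return mx.generate_methylation_cohort(cfg)


@pytest.fixture(scope="session")
def strong_simpo(strong_cohort):
    beta, ann, pheno, truth = strong_cohort
    index = mx.build_gene_region_index(ann, beta)
    simpo = mx.simpo_matrix(beta, index)
    return simpo, pheno, truth
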