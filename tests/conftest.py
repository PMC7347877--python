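import pytest

from domainweaver import pipeline
from domainweaver.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition synthetic dataset (60 domains, seed 7)."""
    cfg = SimConfig()
    ctrl, cko, truth = generate_dataset(cfg)
    return cfg, ctrl, cko, truth


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """Full pipeline run on the default dataset with the planted architecture
    as the per-condition call sets."""
    cfg, ctrl, cko, truth = default_dataset
    domain_calls, loop_calls = pipeline.truth_calls(truth)
    params = pipeline.PipelineParams(
        resolution=cfg.resolution_bp, eigen_resolution=cfg.eigen_resolution_bp,
        seed=cfg.rng_seed,
    )
    return pipeline.run_pipeline(ctrl, cko, domain_calls, loop_calls, params)
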