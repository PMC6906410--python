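import pytest

from annocure.pipeline import PipelineResult, run_pipeline
from annocure.simulate import ScenarioBundle, ScenarioConfig, generate_scenario

# the standard study scenario: a 200-gene toy genome with 30 fusions,
# 20 deleted genes, 15 UTR-hidden genes and 10 frame corruptions
STANDARD = dict(n_genes=200, fusion_count=30, missing_count=20,
                utr_hidden_count=15, misannotation_count=10,
                hit_noise=0.0, seed=1234)


@pytest.fixture(scope="session")
def standard_bundle() -> ScenarioBundle:
    return generate_scenario(ScenarioConfig(**STANDARD))


@pytest.fixture(scope="session")
def standard_result(standard_bundle) -> PipelineResult:
    return run_pipeline(standard_bundle)


@pytest.fixture(scope="session")
def small_bundle() -> ScenarioBundle:
    """A <=100-gene scenario for O(n^2) oracle comparisons."""
    return generate_scenario(ScenarioConfig(
        n_genes=60, n_scaffolds=2, fusion_count=5, missing_count=4,
        utr_hidden_count=3, misannotation_count=2, inparalog_count=3, seed=7))


@pytest.fixture(scope="session")
def noisy_bundle() -> ScenarioBundle:
    return generate_scenario(ScenarioConfig(
        n_genes=80, n_scaffolds=2, fusion_count=6, missing_count=5,
        utr_hidden_count=4, misannotation_count=3, hit_noise=0.15, seed=9))
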