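import pytest

from pimddi.knowledge_base import load_kb
from pimddi.pipeline import run_pipeline
from pimddi.synthetic import GeneratorConfig, generate_cohort, make_worked_example


@pytest.fixture(scope="session")
def kb():
    return load_kb()


@pytest.fixture(scope="session")
def worked_example():
    """Frozen 12-patient cohort plus its hand-verified expected findings."""
    return make_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with ground truth, shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def small_result(small_cohort, kb):
    return run_pipeline(small_cohort.tables, kb)
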