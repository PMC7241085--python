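import pytest
from hypothesis import settings

from iterdda import BatchDesign, generate_batch, generate_library

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from iterdda.benchmark_report import run_benchmark


@pytest.fixture(scope="session")
def small_design():
    """A fast, reduced batch design for unit tests."""
    return BatchDesign(
        n_metabolites=15,
        n_samples=8,
        n_qc_sample_batch=4,
        gradient_length=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_batch(small_design):
    return generate_batch(small_design)


@pytest.fixture(scope="session")
def small_library(small_design):
    return generate_library(small_design.n_metabolites, seed=small_design.seed)


@pytest.fixture(scope="session")
def default_benchmark():
    """One full strategy comparison on the default synthetic batch (seed 1)."""
    return run_benchmark(BatchDesign(seed=1))
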