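import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cleavemap import PipelineConfig, pipeline  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down pipeline configuration for fast end-to-end tests."""
    return PipelineConfig(n_constructs=2, depth_target=400.0, n_molecules=150, seed=11)


@pytest.fixture(scope="session")
def small_run(small_config):
    """References + reads simulated once for the session."""
    refs = pipeline.build_references(small_config)
    reads = pipeline.simulate_readsets(small_config, refs)
    return refs, reads


def brute_force_coverage(starts: np.ndarray, lengths: np.ndarray, L: int) -> np.ndarray:
    """O(L*N) direct membership count: c(n) = #records whose interval contains n."""
    positions = np.arange(1, L + 1)
    ends = starts + lengths - 1
    return (
        (starts[None, :] <= positions[:, None]) & (positions[:, None] <= ends[None, :])
    ).sum(axis=1)
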