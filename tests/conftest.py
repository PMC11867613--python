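import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polypflow.geometry import DomainGrid, build_polyp_profile, canonical_params
from polypflow.pipeline import ScenarioConfig, clear_solve_cache, run_scenario
from polypflow.stokes import SolverConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return build_polyp_profile(canonical_params())


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for solver unit tests: same domain, ~82 um cells."""
    return DomainGrid(nr=61, nz=121)


@pytest.fixture(scope="session")
def small_config(small_grid):
    """Fast scenario configuration for pipeline-level tests."""
    return ScenarioConfig(
        label="3:1",
        solver=SolverConfig(grid=small_grid),
        snapshot_interval=0.25,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_scenario(small_config)


@pytest.fixture(autouse=False)
def fresh_cache():
    clear_solve_cache()
    yield
    clear_solve_cache()
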