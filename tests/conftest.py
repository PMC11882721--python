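import pytest

from orthoconserve import SyntheticWorldConfig, generate_world, benchmark_fixture


@pytest.fixture(scope="session")
def fixture_world():
    """The deterministic benchmark world (built once per session)."""
    return benchmark_fixture()


@pytest.fixture(scope="session")
def fixture_report(fixture_world):
    from orthoconserve import run_pipeline_from_world

    return run_pipeline_from_world(fixture_world)


@pytest.fixture(scope="session")
def small_world():
    """A compact generated world for ground-truth recovery checks."""
    cfg = SyntheticWorldConfig(
        seed=7,
        n_human=1500,
        n_worm=1500,
        focal_size=69,
        edge_density=0.002,
    )
    return generate_world(cfg)
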