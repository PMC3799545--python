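import pytest

from crosspheno import FixtureSpec, generate_fixture, run_pipeline

FIG1_SEED = 7


@pytest.fixture(scope="session")
def fig1_dir(tmp_path_factory):
    """A worked-example fixture directory (shared, read-only)."""
    d = tmp_path_factory.mktemp("fig1")
    generate_fixture(FixtureSpec(seed=FIG1_SEED, include_fig1_cases=True), d)
    return d


@pytest.fixture(scope="session")
def fig1_result(fig1_dir, tmp_path_factory):
    """Pipeline result on the worked-example fixture (shared, read-only)."""
    out = tmp_path_factory.mktemp("fig1_build")
    return run_pipeline(fig1_dir / "config.yaml", out_dir=out)
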