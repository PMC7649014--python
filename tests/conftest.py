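import pytest

from notchkit.pipeline import PipelineConfig, run_pipeline
from notchkit.simulate import compact_roster, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale benchmark: 5 compact clades, 4 members each, no outgroups."""
    return make_benchmark(
        roster=compact_roster(),
        members_per_clade=4,
        seed=7,
        include_outgroups=False,
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full-size pipeline run on the default synthetic family benchmark.

    Shared across tests because the 48 full-length receptors dominate
    runtime; every consumer reads it without mutating artifacts.
    """
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(), out)
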