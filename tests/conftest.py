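import pytest
from hypothesis import HealthCheck, settings

from seascape.pipeline import RunConfig, run_analysis
from seascape.synthetic import SeascapeConfig, simulate

settings.register_profile(
    "seascape",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seascape")


@pytest.fixture(scope="session")
def divergent_dir(tmp_path_factory):
    """Default divergent-regime seascape: 10x10 grid, 25 years, kappa 0->3,
    beta=0.6, written as the pipeline's input CSVs."""
    d = tmp_path_factory.mktemp("divergent")
    simulate(SeascapeConfig(seed=42), d)
    return d


@pytest.fixture(scope="session")
def divergent_result(divergent_dir, tmp_path_factory):
    """Full pipeline result on the divergent-regime seascape, with
    rectangle condition recomputed from the synthetic fish records."""
    out = tmp_path_factory.mktemp("divergent_out")
    config = RunConfig(
        obs_path=divergent_dir / "observations.csv",
        fish_path=divergent_dir / "fish_records.csv",
        outdir=out,
    )
    return run_analysis(config)
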