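import dataclasses

import pytest

from isoforge.pipeline import PipelineConfig, run_pipeline
from isoforge.simulate import (
    DEFAULT_PRIMER3,
    DEFAULT_PRIMER5,
    SimulationConfig,
    TruthSet,
    generate_dataset,
)

PRIMER5 = DEFAULT_PRIMER5
PRIMER3 = DEFAULT_PRIMER3


@pytest.fixture(scope="session")
def zero_noise_config() -> SimulationConfig:
    """The default study conditions with sequencing errors switched off, so
    planted-truth recovery is exact."""
    return SimulationConfig(seed=11, read_error_rate=0.0)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, zero_noise_config):
    """One shared synthetic dataset: (directory, truth)."""
    outdir = tmp_path_factory.mktemp("dataset")
    truth = generate_dataset(zero_noise_config, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, zero_noise_config):
    """One shared full pipeline run on zero-noise data: (report, outdir)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=outdir, simulation=dataclasses.replace(zero_noise_config))
    report = run_pipeline(cfg)
    return report, outdir
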