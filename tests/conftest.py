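import numpy as np
import pytest

from nmpredict import PipelineConfig, SimulationConfig, run_all, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study bundle (150 nucleomorph / 350 nuclear / 100 decoys, seed 7)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_dataset(SimulationConfig(), outdir)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic bundle."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(simulate=True, seed=7)
    manifest = run_all(cfg, outdir)
    return outdir, manifest
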