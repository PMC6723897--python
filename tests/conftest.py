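import numpy as np
import pytest

from dissosurrogate.pipeline import PipelineConfig, run_pipeline
from dissosurrogate.synthetic import SimulatorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study shared by read-only tests."""
    return generate_dataset(SimulatorConfig(seed=11))


@pytest.fixture(scope="session")
def quick_run(tmp_path_factory):
    """The seeded quick end-to-end pipeline run (BR trainer)."""
    out = tmp_path_factory.mktemp("quickrun")
    return run_pipeline(PipelineConfig(seed=7, out_dir=out, profile="quick"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
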