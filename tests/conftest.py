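import pytest

from glycopan.pipeline import RunConfig, run_pipeline
from glycopan.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One default-size synthetic study written to disk (seed 11)."""
    out = tmp_path_factory.mktemp("simdata")
    bundle = simulate_dataset(SimConfig(seed=11), out)
    return out, bundle


@pytest.fixture(scope="session")
def sim_run(sim_dataset, tmp_path_factory):
    """Full pipeline run on the session dataset (reduced permutations)."""
    data_dir, bundle = sim_dataset
    out = tmp_path_factory.mktemp("simrun")
    cfg = RunConfig.from_dataset(data_dir, out, seed=11, n_permutations=5000)
    summary = run_pipeline(cfg)
    return out, bundle, summary
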