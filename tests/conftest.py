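import pytest

from evtx.pipeline import PipelineConfig, run_pipeline, simulate
from evtx.simdata import SimConfig, make_reference, simulate_sample


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11, n_reads=20_000)


@pytest.fixture(scope="session")
def bundle(sim_config):
    return make_reference(sim_config)


@pytest.fixture(scope="session")
def sample(bundle, sim_config):
    return simulate_sample(bundle, sim_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, sim_config):
    """One full synthetic run (fixture files + pipeline report), shared."""
    out = tmp_path_factory.mktemp("simrun")
    paths = simulate(sim_config, out)
    config = PipelineConfig.from_yaml(paths["config"])
    report = run_pipeline(config, paths["fastq"], paths["sam"], out_dir=out / "report")
    return {"paths": paths, "config": config, "report": report, "dir": out}
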