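import pytest

from genovuln.simulate import SimulationConfig, generate_specimen, write_specimen


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=80, het_snv_rate=0.002, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_specimen(small_config, "syn", "sp1")


@pytest.fixture(scope="session")
def small_bundle_paths(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_specimen(small_bundle, outdir)
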