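import pytest
from hypothesis import settings

from ecotoxrank.synthetic_data import GeneratorConfig, simulate_tables

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ecotoxrank import synthetic_data


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_config):
    """All six synthetic CSV tables written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = simulate_tables(default_config, outdir)
    return paths


@pytest.fixture(scope="session")
def catalog(default_config):
    return synthetic_data.generate_catalog(default_config)


@pytest.fixture(scope="session")
def sites(default_config):
    return synthetic_data.generate_sites(default_config)


@pytest.fixture(scope="session")
def measurements(default_config, catalog, sites):
    substances, _ = catalog
    return synthetic_data.generate_measurements(default_config, substances, sites)
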