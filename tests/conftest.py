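import pytest

from lgtscan.synthetic import (SPECIES_TAXIDS, GeneratorConfig,
                               build_default_taxonomy, generate)


@pytest.fixture(scope="session")
def tax():
    return build_default_taxonomy()


@pytest.fixture(scope="session")
def species_taxids():
    return dict(SPECIES_TAXIDS)


@pytest.fixture(scope="session")
def small_bundle():
    """The default small synthetic study (seed 1)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    small_bundle.write(d)
    return d
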