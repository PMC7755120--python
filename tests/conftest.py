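import pytest

from mttrna.classify import screen
from mttrna.io import bundled_variant_table, bundled_variants
from mttrna.model import load_gene_definitions


@pytest.fixture(scope="session")
def genes():
    return load_gene_definitions()


@pytest.fixture(scope="session")
def variants():
    return bundled_variants()


@pytest.fixture(scope="session")
def variant_table():
    """Raw bundled cohort table, including the published tRNA-position,
    location and pairing columns used as golden expectations."""
    return bundled_variant_table()


@pytest.fixture(scope="session")
def report(genes, variants):
    return screen(variants, genes, n_cases=494, n_controls=485)
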