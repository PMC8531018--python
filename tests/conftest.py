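import pytest

from pantx.synthetic_fixtures import (
    gen_decontam_fixture,
    gen_expression_fixture,
    gen_orf_fixture,
    gen_unify_fixture,
    gen_variant_fixture,
)


@pytest.fixture(scope="session")
def unify_fixture():
    return gen_unify_fixture(seed=1, n_base=50, n_unique=3, n_redundant=2, n_bridges=1)


@pytest.fixture(scope="session")
def orf_fixture():
    return gen_orf_fixture(seed=1, n_coding=10, n_noncoding=5, n_chimera=3)


@pytest.fixture(scope="session")
def variant_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("variants")
    return gen_variant_fixture(seed=1, n_strains=4, n_records=40, out_dir=out)


@pytest.fixture(scope="session")
def decontam_fixture():
    return gen_decontam_fixture(seed=1, n_loci=50, n_contam=5)


@pytest.fixture(scope="session")
def expression_fixture():
    return gen_expression_fixture(seed=1, n_genes=200)
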