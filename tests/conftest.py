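import pytest

from ontoforge.fixtures import (
    SyntheticSpec,
    gene_example,
    materialize,
    molecule_example,
    protein_pattern_examples,
    run_bundle,
    run_integration,
    synthetic_pair,
)


@pytest.fixture(scope="session")
def gene_bundle():
    return gene_example()


@pytest.fixture(scope="session")
def gene_mat(gene_bundle):
    return materialize(gene_bundle)


@pytest.fixture(scope="session")
def gene_result(gene_bundle):
    return run_bundle(gene_bundle)


@pytest.fixture(scope="session")
def molecule_result():
    return run_bundle(molecule_example())


@pytest.fixture(scope="session")
def protein_results():
    with_cds, without_cds = protein_pattern_examples()
    return run_bundle(with_cds), run_bundle(without_cds)


@pytest.fixture(scope="session")
def synthetic_merge_run():
    spec = SyntheticSpec(seed=0, n_entities=100, duplicate_rate=0.2,
                         overlap=30)
    a, b, truth = synthetic_pair(spec)
    return run_integration([a, b]), (a, b), truth


@pytest.fixture(scope="session")
def synthetic_link_run():
    spec = SyntheticSpec(seed=0, n_entities=100, duplicate_rate=0.2,
                         overlap=30)
    a, b, truth = synthetic_pair(spec, behaviour="link")
    return run_integration([a, b]), (a, b), truth
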