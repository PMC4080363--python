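import pytest

from maxcom import (
    AssociationList,
    BenchmarkSpec,
    PPIEdgeList,
    SimilarityTable,
    ProteinComplex,
    build_network,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced benchmark world for fast unit tests."""
    return BenchmarkSpec(
        n_diseases=60,
        n_disease_families=6,
        n_proteins=300,
        n_complexes=18,
        module_size=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_benchmark(small_spec):
    return generate_benchmark(small_spec)


@pytest.fixture(scope="session")
def small_network(small_benchmark):
    sim, ppi, assoc, complexes, truth = small_benchmark
    return build_network(sim, ppi, assoc, alpha=0.1)


@pytest.fixture()
def toy_layers():
    """Two diseases, two proteins, one association: hand-checkable flows.

    d1 --0.5-- d2;  d2 -> p (association);  q isolated in the PPI.
    """
    sim = SimilarityTable.from_records([("d1", "d2", 0.5)])
    ppi = PPIEdgeList.from_records([], proteins=["p", "q"])
    assoc = AssociationList.from_records([("d2", "p")])
    return sim, ppi, assoc


@pytest.fixture()
def toy_network(toy_layers):
    sim, ppi, assoc = toy_layers
    return build_network(sim, ppi, assoc, alpha=0.1)


@pytest.fixture()
def complex_p():
    return ProteinComplex(complex_id="C1", members=frozenset({"p"}))


@pytest.fixture()
def complex_pq():
    return ProteinComplex(complex_id="C2", members=frozenset({"p", "q"}))
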