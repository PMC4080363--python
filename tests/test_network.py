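"""Heterogeneous network assembly: capacities, alpha filter, big-M, sinks."""

import pytest

from maxcom import (
    AssociationList,
    PPIEdgeList,
    ProteinComplex,
    SimilarityTable,
    attach_complex_sink,
    build_network,
    compute_big_m,
    detach_sink,
)
from maxcom.network import SINK


class TestLayerTypes:
    def test_similarity_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            SimilarityTable.from_records([("a", "b", 1.2)])

    def test_similarity_rejects_self_pair(self):
        with pytest.raises(ValueError):
            SimilarityTable.from_records([("a", "a", 0.5)])

    def test_similarity_merges_symmetric_duplicates(self):
        sim = SimilarityTable.from_records([("a", "b", 0.5), ("b", "a", 0.5)])
        assert len(sim) == 1

    def test_similarity_conflicting_duplicates_raise(self):
        with pytest.raises(ValueError):
            SimilarityTable.from_records([("a", "b", 0.5), ("b", "a", 0.6)])

    def test_mean_similarity_with_and_without_zeros(self):
        sim = SimilarityTable.from_records(
            [("a", "b", 0.4)], diseases=["a", "b", "c"]
        )
        assert sim.mean_similarity() == pytest.approx(0.4)
        # three diseases -> three unordered pairs, two of them zero
        assert sim.mean_similarity(include_zeros=True) == pytest.approx(0.4 / 3)

    def test_ppi_rejects_self_interaction(self):
        with pytest.raises(ValueError):
            PPIEdgeList.from_records([("p", "p")])

    def test_ppi_dedup(self):
        ppi = PPIEdgeList.from_records([("a", "b"), ("b", "a")])
        assert len(ppi) == 1

    def test_complex_requires_members(self):
        with pytest.raises(ValueError):
            ProteinComplex(complex_id="X", members=frozenset())


class TestComputeBigM:
    def test_definition(self):
        assert compute_big_m(10.5) == pytest.approx(11.5)
        assert compute_big_m(0.0) == pytest.approx(1.0)

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            compute_big_m(-1.0)


class TestBuildNetwork:
    def test_alpha_filters_weak_similarities(self):
        sim = SimilarityTable.from_records([("a", "b", 0.05), ("a", "c", 0.3)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        assoc = AssociationList.from_records([("a", "p")])
        net = build_network(sim, ppi, assoc, alpha=0.1)
        assert ("a", "b") not in net.dd
        assert net.dd[("a", "c")] == pytest.approx(0.3)

    def test_alpha_zero_keeps_all_nonzero_pairs(self):
        sim = SimilarityTable.from_records([("a", "b", 0.05), ("a", "c", 0.3)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        assoc = AssociationList.from_records([("a", "p")])
        net = build_network(sim, ppi, assoc, alpha=0.0)
        assert set(net.dd) == {("a", "b"), ("a", "c")}

    def test_zero_similarity_never_becomes_an_arc(self):
        sim = SimilarityTable.from_records([("a", "b", 0.0), ("a", "c", 0.3)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        assoc = AssociationList.from_records([("a", "p")])
        net = build_network(sim, ppi, assoc, alpha=0.0)
        assert ("a", "b") not in net.dd

    def test_ppi_arcs_have_unit_capacity_both_directions(self, toy_network):
        fn = toy_network.flow_network
        # the toy network has no PPI edges; check on a fresh build
        sim = SimilarityTable.from_records([("a", "b", 0.5)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        assoc = AssociationList.from_records([("a", "p")])
        fn = build_network(sim, ppi, assoc).flow_network
        assert fn.capacity("p", "q") == 1.0
        assert fn.capacity("q", "p") == 1.0

    def test_association_arcs_directed_at_big_m(self, toy_network):
        fn = toy_network.flow_network
        assert fn.capacity("d2", "p") == toy_network.big_m
        assert not fn.has_arc("p", "d2")

    def test_big_m_dominates_finite_capacity(self, small_network):
        assert small_network.big_m > small_network.finite_capacity_total()

    def test_unknown_association_ids_dropped_with_warning(self, caplog):
        sim = SimilarityTable.from_records([("a", "b", 0.5)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        assoc = AssociationList.from_records([("a", "p"), ("ghost", "p"), ("a", "zz")])
        with caplog.at_level("WARNING", logger="maxcom"):
            net = build_network(sim, ppi, assoc)
        assert net.dp == frozenset({("a", "p")})
        assert "dropped 2" in caplog.text

    def test_empty_layers_rejected(self):
        sim = SimilarityTable.from_records([("a", "b", 0.5)])
        ppi = PPIEdgeList.from_records([("p", "q")])
        with pytest.raises(ValueError):
            build_network(sim, ppi, AssociationList(pairs=frozenset()))
        with pytest.raises(ValueError):
            build_network(sim, ppi, AssociationList.from_records([("a", "p")]), alpha=1.5)

    def test_node_class_partition_is_total(self, small_network):
        classes = small_network.node_class
        assert set(classes) == set(small_network.diseases) | set(small_network.proteins)
        assert set(classes.values()) == {"disease", "protein"}

    def test_build_is_deterministic(self, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        a = build_network(sim, ppi, assoc, alpha=0.1)
        b = build_network(sim, ppi, assoc, alpha=0.1)
        assert a.digest() == b.digest()

    def test_raising_alpha_never_adds_disease_arcs(self, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        counts = [
            len(build_network(sim, ppi, assoc, alpha=a).dd)
            for a in (0.0, 0.1, 0.2, 0.3, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # some similarity lies in between


class TestSinkAttachment:
    def test_all_members_present(self, toy_network, complex_pq):
        fn = attach_complex_sink(toy_network, complex_pq)
        assert fn.capacity("p", SINK) == toy_network.big_m
        assert fn.capacity("q", SINK) == toy_network.big_m

    def test_absent_members_skipped(self, toy_network):
        c = ProteinComplex(complex_id="C", members=frozenset({"p", "nope"}))
        fn = attach_complex_sink(toy_network, c)
        assert fn.capacity("p", SINK) == toy_network.big_m
        assert not fn.has_arc("nope", SINK)

    def test_no_member_present_isolated_sink(self, toy_network, caplog):
        c = ProteinComplex(complex_id="C", members=frozenset({"nope"}))
        with caplog.at_level("WARNING", logger="maxcom"):
            fn = attach_complex_sink(toy_network, c)
        assert SINK in fn
        assert all(SINK not in arc for arc in fn.arcs)

    def test_attach_then_detach_is_identity(self, toy_network, complex_pq):
        fn = attach_complex_sink(toy_network, complex_pq)
        back = detach_sink(fn)
        assert back.arcs == toy_network.flow_network.arcs

    def test_original_network_unmodified(self, toy_network, complex_p):
        before = set(toy_network.flow_network.arcs)
        attach_complex_sink(toy_network, complex_p)
        assert set(toy_network.flow_network.arcs) == before


class TestHoldout:
    def test_drop_associations_touching_members(self, small_network):
        some_protein = next(iter(small_network.dp))[1]
        patched = small_network.drop_associations_touching([some_protein])
        assert all(p != some_protein for _, p in patched.dp)
        # only association arcs differ; nodes and other layers identical
        assert patched.diseases == small_network.diseases
        assert patched.pp == small_network.pp
        assert patched.dd == small_network.dd
        assert patched.big_m == small_network.big_m
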