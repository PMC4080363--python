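"""Solver correctness: push-relabel vs Edmonds-Karp oracle vs brute-force cuts."""

import numpy as np
import pytest

from maxcom.flow import (
    FlowNetwork,
    FlowResult,
    _max_flow_igraph,
    max_flow,
    max_flow_reference,
    min_cut_bruteforce,
    verify_flow,
)


def chain_network():
    net = FlowNetwork()
    net.add_arc("s", "a", 2.0)
    net.add_arc("a", "t", 5.0)
    return net


def random_network(rng, n_nodes, n_arcs, cap_max=10):
    net = FlowNetwork(nodes=range(n_nodes))
    for _ in range(n_arcs):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            net.add_arc(int(u), int(v), int(rng.integers(1, cap_max + 1)))
    return net


class TestFlowNetwork:
    def test_rejects_self_loops_and_bad_capacities(self):
        net = FlowNetwork()
        with pytest.raises(ValueError):
            net.add_arc("a", "a", 1.0)
        with pytest.raises(ValueError):
            net.add_arc("a", "b", -0.5)
        with pytest.raises(ValueError):
            net.add_arc("a", "b", float("inf"))

    def test_undirected_edge_becomes_antiparallel_pair(self):
        net = FlowNetwork()
        net.add_undirected_edge("a", "b", 0.7)
        assert net.arcs == {("a", "b"): 0.7, ("b", "a"): 0.7}

    def test_tsv_round_trip(self, tmp_path):
        net = chain_network()
        path = tmp_path / "net.tsv"
        net.to_tsv(path)
        back = FlowNetwork.from_tsv(path)
        assert back.arcs == net.arcs


class TestMaxFlowExamples:
    @pytest.mark.parametrize("method", ["push_relabel", "igraph"])
    def test_chain_bottleneck(self, method):
        net = chain_network()
        res = max_flow(net, "s", "t", method=method)
        assert res.value == pytest.approx(2.0, abs=1e-9)
        assert verify_flow(net, res)

    @pytest.mark.parametrize("method", ["push_relabel", "igraph"])
    def test_disconnected_terminals(self, method):
        net = FlowNetwork(nodes=["s", "t"])
        net.add_arc("s", "a", 3.0)
        res = max_flow(net, "s", "t", method=method)
        assert res.value == 0.0

    def test_reference_chain_and_empty(self):
        assert max_flow_reference(chain_network(), "s", "t").value == pytest.approx(2.0)
        empty = FlowNetwork(nodes=["s", "t"])
        assert max_flow_reference(empty, "s", "t").value == 0.0

    def test_reference_complete_graph_k4_unit_caps(self):
        # min cut isolates one terminal: 3 unit arcs
        net = FlowNetwork()
        for u in range(1, 5):
            for v in range(1, 5):
                if u != v:
                    net.add_arc(u, v, 1.0)
        assert max_flow_reference(net, 1, 4).value == pytest.approx(3.0)
        assert min_cut_bruteforce(net, 1, 4) == pytest.approx(3.0)

    def test_unknown_terminal_raises(self):
        net = chain_network()
        with pytest.raises(KeyError):
            max_flow(net, "nope", "t")
        with pytest.raises(KeyError):
            max_flow_reference(net, "s", "nope")

    def test_identical_terminals_raise(self):
        with pytest.raises(ValueError):
            max_flow(chain_network(), "s", "s")


class TestMinCutBruteforce:
    def test_chain(self):
        assert min_cut_bruteforce(chain_network(), "s", "t") == pytest.approx(2.0)

    def test_diamond_two_disjoint_paths(self):
        net = FlowNetwork()
        for mid in ("a", "b"):
            net.add_arc("s", mid, 1.0)
            net.add_arc(mid, "t", 1.0)
        assert min_cut_bruteforce(net, "s", "t") == pytest.approx(2.0)

    def test_disconnected_is_zero(self):
        net = FlowNetwork(nodes=["s", "t", "x"])
        net.add_arc("s", "x", 4.0)
        assert min_cut_bruteforce(net, "s", "t") == 0.0

    def test_size_limit(self):
        net = FlowNetwork(nodes=range(25))
        net.add_arc(0, 24, 1.0)
        with pytest.raises(ValueError):
            min_cut_bruteforce(net, 0, 24)


class TestVerifyFlow:
    def test_accepts_solver_output(self):
        net = chain_network()
        assert verify_flow(net, max_flow(net, "s", "t"))

    def test_rejects_capacity_violation(self):
        net = chain_network()
        res = FlowResult(3.0, {("s", "a"): 3.0, ("a", "t"): 3.0}, "s", "t")
        assert not verify_flow(net, res)

    def test_rejects_conservation_violation(self):
        net = chain_network()
        res = FlowResult(2.0, {("s", "a"): 2.0, ("a", "t"): 1.0}, "s", "t")
        assert not verify_flow(net, res)

    def test_rejects_foreign_arc(self):
        net = chain_network()
        res = FlowResult(0.0, {("t", "s"): 0.0}, "s", "t")
        assert not verify_flow(net, res)


class TestSolverAgreement:
    """Randomized cross-validation of all solver routes (fixed seed schedule)."""

    def test_push_relabel_matches_edmonds_karp_500_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(4, 13))
            m = int(rng.integers(4, 31))
            net = random_network(rng, n, m)
            got = max_flow(net, 0, n - 1)
            want = max_flow_reference(net, 0, n - 1)
            assert got.value == pytest.approx(want.value, abs=1e-9)
            assert verify_flow(net, got)
            assert verify_flow(net, want)

    def test_flow_value_matches_bruteforce_min_cut_200_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            m = int(rng.integers(4, 25))
            net = random_network(rng, n, m)
            value = max_flow(net, 0, n - 1).value
            assert value == pytest.approx(min_cut_bruteforce(net, 0, n - 1), abs=1e-9)

    def test_igraph_backend_agrees_with_push_relabel(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            net = random_network(rng, n, int(rng.integers(4, 28)))
            a = max_flow(net, 0, n - 1, method="push_relabel")
            b = _max_flow_igraph(net, 0, n - 1)
            assert a.value == pytest.approx(b.value, abs=1e-9)
            assert verify_flow(net, b)

    def test_real_valued_capacities(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            net = FlowNetwork(nodes=range(n))
            for _ in range(int(rng.integers(4, 20))):
                u, v = rng.integers(0, n, size=2)
                if u != v:
                    net.add_arc(int(u), int(v), float(rng.uniform(0.01, 5.0)))
            got = max_flow(net, 0, n - 1)
            want = max_flow_reference(net, 0, n - 1)
            assert got.value == pytest.approx(want.value, abs=1e-9)
            assert verify_flow(net, got)


class TestFlowProperties:
    def test_monotone_in_capacity(self):
        # raising any single arc capacity never lowers the max-flow value
        rng = np.random.default_rng(23)
        for _ in range(60):
            n = int(rng.integers(4, 10))
            net = random_network(rng, n, int(rng.integers(5, 20)))
            base = max_flow(net, 0, n - 1).value
            arcs = list(net.arcs)
            if not arcs:
                continue
            u, v = arcs[int(rng.integers(len(arcs)))]
            bumped = net.copy()
            bumped.add_arc(u, v, net.capacity(u, v) + float(rng.uniform(0.5, 3.0)))
            assert max_flow(bumped, 0, n - 1).value >= base - 1e-9

    def test_integer_capacities_give_integer_value(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            net = random_network(rng, n, int(rng.integers(4, 30)))
            value = max_flow(net, 0, n - 1).value
            assert abs(value - round(value)) < 1e-9

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(31)
        net = random_network(rng, 10, 25)
        first = max_flow(net, 0, 9)
        second = max_flow(net, 0, 9)
        assert first.value == second.value
        assert first.arc_flow == second.arc_flow
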