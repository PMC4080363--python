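"""Arc-capacitated directed graphs and exact maximum-flow solvers.

The information-flow score at the heart of this package is a plain
single-commodity maximum flow: every edge of the heterogeneous
disease-protein network carries a nonnegative capacity, and the score of a
candidate complex is the largest total flow that can be routed from the
query disease to a sink attached behind the complex members.

This module provides the graph container (:class:`FlowNetwork`), a
production solver (:func:`max_flow`) with two interchangeable backends --
a from-scratch highest-label push-relabel with the gap heuristic, and
igraph's C implementation of the same Goldberg-Tarjan family -- plus two
independent cross-checks used by the test-suite: a shortest-augmenting-path
(Edmonds-Karp) oracle built on networkx (:func:`max_flow_reference`) and an
exponential min-cut enumerator (:func:`min_cut_bruteforce`).

Undirected input edges are represented as two antiparallel arcs, each
carrying the full edge capacity.  All capacities are handled in floating
point with a 1e-9 feasibility tolerance; iteration orders are sorted by
node id so repeated runs are bit-identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, Mapping, Optional, Tuple

import igraph as ig
import networkx as nx

Node = Hashable
Arc = Tuple[Node, Node]

#: feasibility tolerance used throughout (capacity bounds, conservation)
TOL = 1e-9

# internal tolerance for "is there residual capacity left" decisions;
# tighter than TOL so rounding never stalls the solver
_EPS = 1e-12


class FlowNetwork:
    """Directed graph with nonnegative finite arc capacities.

    Parameters
    ----------
    arcs:
        Mapping ``(u, v) -> capacity`` or iterable of ``(u, v, capacity)``
        triples.  Self-loops and negative/non-finite capacities are
        rejected.  At most one arc per ordered pair; re-adding an arc
        overwrites its capacity.
    nodes:
        Extra isolated nodes to include beyond arc endpoints.
    source, sink:
        Optional designated terminals (informational; the solvers take
        explicit terminals).
    """

    __slots__ = ("_arcs", "_nodes", "source", "sink")

    def __init__(
        self,
        arcs: Mapping[Arc, float] | Iterable[Tuple[Node, Node, float]] = (),
        nodes: Iterable[Node] = (),
        source: Optional[Node] = None,
        sink: Optional[Node] = None,
    ) -> None:
        self._arcs: Dict[Arc, float] = {}
        self._nodes: set = set(nodes)
        self.source = source
        self.sink = sink
        if isinstance(arcs, Mapping):
            items: Iterable[Tuple[Node, Node, float]] = (
                (u, v, c) for (u, v), c in arcs.items()
            )
        else:
            items = arcs
        for u, v, c in items:
            self.add_arc(u, v, c)

    # -- construction ---------------------------------------------------

    def add_node(self, u: Node) -> None:
        self._nodes.add(u)

    def add_arc(self, u: Node, v: Node, capacity: float) -> None:
        """Add (or overwrite) the arc ``u -> v``."""
        if u == v:
            raise ValueError(f"self-loop arc on node {u!r} is not allowed")
        c = float(capacity)
        if not math.isfinite(c) or c < 0:
            raise ValueError(
                f"arc ({u!r}, {v!r}) has invalid capacity {capacity!r}; "
                "capacities must be finite and >= 0"
            )
        self._arcs[(u, v)] = c
        self._nodes.add(u)
        self._nodes.add(v)

    def add_undirected_edge(self, u: Node, v: Node, capacity: float) -> None:
        """Insert an undirected edge as two antiparallel arcs of equal capacity."""
        self.add_arc(u, v, capacity)
        self.add_arc(v, u, capacity)

    def remove_arc(self, u: Node, v: Node) -> None:
        del self._arcs[(u, v)]

    def copy(self) -> "FlowNetwork":
        out = FlowNetwork(source=self.source, sink=self.sink)
        out._arcs = dict(self._arcs)
        out._nodes = set(self._nodes)
        return out

    # -- inspection ------------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._nodes)

    @property
    def arcs(self) -> Dict[Arc, float]:
        return dict(self._arcs)

    def capacity(self, u: Node, v: Node) -> float:
        return self._arcs[(u, v)]

    def has_arc(self, u: Node, v: Node) -> bool:
        return (u, v) in self._arcs

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_arcs(self) -> int:
        return len(self._arcs)

    def sorted_nodes(self) -> list:
        return sorted(self._nodes, key=repr)

    def sorted_arcs(self) -> list:
        return sorted(self._arcs.items(), key=lambda kv: (repr(kv[0][0]), repr(kv[0][1])))

    def __contains__(self, u: Node) -> bool:
        return u in self._nodes

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"FlowNetwork(n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"

    # -- plain-text debug dump ------------------------------------------

    def to_tsv(self, path) -> None:
        """Write arcs as a ``u<TAB>v<TAB>capacity`` table."""
        with open(path, "w") as fh:
            fh.write("u\tv\tcapacity\n")
            for (u, v), c in self.sorted_arcs():
                fh.write(f"{u}\t{v}\t{c:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FlowNetwork":
        net = cls()
        with open(path) as fh:
            header = fh.readline()
            if header and not header.startswith("u\t"):
                # headerless dump
                u, v, c = header.rstrip("\n").split("\t")
                net.add_arc(u, v, float(c))
            for line in fh:
                if not line.strip():
                    continue
                u, v, c = line.rstrip("\n").split("\t")
                net.add_arc(u, v, float(c))
        return net


@dataclass(frozen=True)
class FlowResult:
    """A feasible flow: total value plus per-arc flow assignment."""

    value: float
    arc_flow: Mapping[Arc, float]
    source: Node
    sink: Node


def _check_terminals(network: FlowNetwork, source: Node, sink: Node) -> None:
    if source not in network:
        raise KeyError(f"unknown source node {source!r}")
    if sink not in network:
        raise KeyError(f"unknown sink node {sink!r}")
    if source == sink:
        raise ValueError("source and sink must be distinct")


def max_flow(
    network: FlowNetwork,
    source: Node,
    sink: Node,
    method: str = "push_relabel",
) -> FlowResult:
    """Compute a maximum ``source -> sink`` flow.

    ``method="push_relabel"`` runs the package's own highest-label
    push-relabel with the gap heuristic; ``method="igraph"`` delegates to
    igraph's C push-relabel (used by the scoring engine for speed).  Both
    return identical flow values; the arc-flow decomposition may differ
    (it is not unique).
    """
    _check_terminals(network, source, sink)
    if method == "push_relabel":
        return _max_flow_push_relabel(network, source, sink)
    if method == "igraph":
        return _max_flow_igraph(network, source, sink)
    raise ValueError(f"unknown max-flow method {method!r}")


def _max_flow_push_relabel(network: FlowNetwork, source: Node, sink: Node) -> FlowResult:
    nodes = network.sorted_nodes()
    idx = {u: i for i, u in enumerate(nodes)}
    arcs = network.sorted_arcs()
    n = len(nodes)
    s, t = idx[source], idx[sink]

    # residual edge arrays; original arc k -> edge 2k, reverse 2k+1
    m2 = 2 * len(arcs)
    to = [0] * m2
    cap = [0.0] * m2
    flw = [0.0] * m2
    adj: list = [[] for _ in range(n)]
    for k, ((u, v), c) in enumerate(arcs):
        e = 2 * k
        ui, vi = idx[u], idx[v]
        to[e] = vi
        cap[e] = c
        to[e + 1] = ui
        adj[ui].append(e)
        adj[vi].append(e + 1)

    H = 2 * n
    height = [0] * n
    height[s] = n
    excess = [0.0] * n
    count = [0] * (H + 2)
    count[0] = n - 1
    count[n] += 1
    cur = [0] * n
    buckets: list = [[] for _ in range(H + 1)]
    queued = [False] * n

    def activate(v: int) -> None:
        if v != s and v != t and not queued[v] and excess[v] > _EPS:
            buckets[height[v]].append(v)
            queued[v] = True

    # saturate source-incident arcs
    for e in adj[s]:
        if e % 2 == 0:
            d = cap[e] - flw[e]
            if d > _EPS:
                v = to[e]
                flw[e] += d
                flw[e ^ 1] -= d
                excess[s] -= d
                excess[v] += d
                activate(v)

    hi = H
    while True:
        while hi >= 0 and not buckets[hi]:
            hi -= 1
        if hi < 0:
            break
        u = buckets[hi].pop()
        queued[u] = False
        if excess[u] <= _EPS or u == s or u == t:
            continue
        if height[u] != hi:
            # stale bucket entry after a relabel/gap lift: requeue at the
            # node's current height
            activate(u)
            continue
        # discharge u completely
        while excess[u] > _EPS:
            if cur[u] == len(adj[u]):
                # relabel
                old = height[u]
                nh = H
                for e in adj[u]:
                    if cap[e] - flw[e] > _EPS:
                        nh = min(nh, height[to[e]] + 1)
                count[old] -= 1
                if count[old] == 0 and 0 < old < n:
                    # gap heuristic: heights in (old, n) are unreachable
                    # from the sink side; lift those nodes past n
                    for v in range(n):
                        if v != s and old < height[v] < n:
                            count[height[v]] -= 1
                            height[v] = n + 1
                            count[n + 1] += 1
                    if old < nh < n:
                        nh = n + 1
                if nh >= H:
                    # no residual arc at all: excess cannot move (should
                    # not happen for reachable nodes); park the node
                    count[old] += 1  # undo decrement bookkeeping
                    height[u] = old
                    break
                height[u] = nh
                count[nh] += 1
                cur[u] = 0
            else:
                e = adj[u][cur[u]]
                v = to[e]
                r = cap[e] - flw[e]
                if r > _EPS and height[u] == height[v] + 1:
                    d = excess[u] if excess[u] < r else r
                    flw[e] += d
                    flw[e ^ 1] -= d
                    excess[u] -= d
                    excess[v] += d
                    activate(v)
                else:
                    cur[u] += 1
        if excess[u] > _EPS:
            activate(u)
        if height[u] > hi:
            hi = height[u]

    value = excess[t]
    arc_flow: Dict[Arc, float] = {}
    for k, ((u, v), c) in enumerate(arcs):
        f = flw[2 * k]
        if f < 0.0:
            f = 0.0
        elif f > c:
            f = c
        arc_flow[(u, v)] = f
    return FlowResult(value=value, arc_flow=arc_flow, source=source, sink=sink)


def _max_flow_igraph(network: FlowNetwork, source: Node, sink: Node) -> FlowResult:
    nodes = network.sorted_nodes()
    idx = {u: i for i, u in enumerate(nodes)}
    arcs = network.sorted_arcs()
    g = ig.Graph(
        len(nodes), [(idx[u], idx[v]) for (u, v), _ in arcs], directed=True
    )
    mf = g.maxflow(idx[source], idx[sink], capacity=[c for _, c in arcs])
    arc_flow: Dict[Arc, float] = {}
    for ((u, v), c), f in zip(arcs, mf.flow):
        arc_flow[(u, v)] = min(max(float(f), 0.0), c)
    return FlowResult(value=float(mf.value), arc_flow=arc_flow, source=source, sink=sink)


def max_flow_reference(network: FlowNetwork, source: Node, sink: Node) -> FlowResult:
    """Independent shortest-augmenting-path (Edmonds-Karp) oracle.

    Built on :mod:`networkx`; intended for tests and small instances only.
    """
    _check_terminals(network, source, sink)
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for (u, v), c in network.arcs.items():
        g.add_edge(u, v, capacity=c)
    value, flow_dict = nx.maximum_flow(
        g, source, sink, flow_func=nx.algorithms.flow.edmonds_karp
    )
    arc_flow = {
        (u, v): float(flow_dict.get(u, {}).get(v, 0.0)) for (u, v) in network.arcs
    }
    return FlowResult(value=float(value), arc_flow=arc_flow, source=source, sink=sink)


def min_cut_bruteforce(network: FlowNetwork, source: Node, sink: Node) -> float:
    """Exact min s-t cut by enumerating all source-side node subsets.

    Exponential: limited to networks with at most 20 nodes.
    """
    _check_terminals(network, source, sink)
    nodes = [u for u in network.sorted_nodes() if u not in (source, sink)]
    if len(nodes) + 2 > 20:
        raise ValueError(
            f"min_cut_bruteforce limited to 20 nodes, got {len(nodes) + 2}"
        )
    arcs = network.sorted_arcs()
    best = math.inf
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            side = {source, *subset}
            cut = 0.0
            for (u, v), c in arcs:
                if u in side and v not in side:
                    cut += c
            if cut < best:
                best = cut
    return best


def verify_flow(network: FlowNetwork, result: FlowResult, tol: float = TOL) -> bool:
    """Check capacity bounds, conservation and value consistency.

    Returns ``False`` (never raises) when any constraint is violated by
    more than ``tol``.  Arcs carrying flow must be a subset of the
    network's arcs.
    """
    arcs = network.arcs
    net_flux: Dict[Node, float] = {u: 0.0 for u in network.nodes}
    for (u, v), f in result.arc_flow.items():
        if (u, v) not in arcs:
            return False
        if f < -tol or f > arcs[(u, v)] + tol:
            return False
        net_flux[u] -= f
        net_flux[v] += f
    s, t = result.source, result.sink
    if s not in net_flux or t not in net_flux:
        return False
    for u, b in net_flux.items():
        if u in (s, t):
            continue
        if abs(b) > tol:
            return False
    if abs(-net_flux[s] - result.value) > tol:
        return False
    if abs(net_flux[t] - result.value) > tol:
        return False
    return True
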