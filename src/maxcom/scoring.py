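"""Maximum-information-flow scoring and ranking of candidate complexes.

The MIF of complex :math:`C_i` for a query disease is the maximum-flow
value from the query node to a sink attached behind the complex, divided
by the number of member proteins :math:`|C_i|`:

.. math::  \\mathrm{MIF}(i) = \\frac{1}{|C_i|} \\sum_j f_{\\mathrm{sink}_j}

where the sum of per-member sink-arc flows equals the scalar max-flow
value.  Members absent from the network contribute zero flow but, under
the default ``denominator="annotated"`` policy, still count in the
denominator.

:class:`MIFEngine` is the fast scoring path: it builds one igraph graph
holding every arc of the heterogeneous network *plus* a zero-capacity
sink arc for every protein, then scores each (query, complex) pair by a
single C max-flow call on a per-call capacity vector (member sink arcs
raised to big_m, held-out association arcs zeroed).  This is
mathematically identical to attaching/detaching a per-complex sink, and
is cross-checked against the attach-and-solve route in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import igraph as ig
import numpy as np
from scipy.stats import rankdata

from .flow import FlowNetwork, FlowResult, max_flow
from .network import (
    SINK,
    HeterogeneousNetwork,
    ProteinComplex,
    attach_complex_sink,
)

logger = logging.getLogger("maxcom")


@dataclass(frozen=True)
class ComplexScore:
    """Per-complex MIF value and (optional) rank position."""

    complex_id: str
    mif: float
    n_members: int
    n_members_in_network: int
    rank: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mif < 0:
            raise ValueError("mif must be >= 0")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.n_members_in_network > self.n_members:
            raise ValueError("n_members_in_network cannot exceed n_members")


class MIFEngine:
    """Reusable max-flow engine for one heterogeneous network.

    Builds the igraph representation once; every protein has a
    pre-allocated arc to a shared sink whose capacity is 0 except for the
    members of the complex currently being scored.
    """

    def __init__(self, network: HeterogeneousNetwork) -> None:
        self.network = network
        nodes: List[str] = list(network.diseases) + list(network.proteins)
        self._idx = {u: i for i, u in enumerate(nodes)}
        self._nodes = nodes
        self._disease_set = frozenset(network.diseases)
        self._protein_set = frozenset(network.proteins)
        self._sink = len(nodes)

        edges: List[Tuple[int, int]] = []
        caps: List[float] = []
        self._arc_names: List[Tuple[str, str]] = []

        def add(u: str, v: str, c: float) -> int:
            edges.append((self._idx[u], self._idx[v]))
            caps.append(c)
            self._arc_names.append((u, v))
            return len(edges) - 1

        for (a, b), s in sorted(network.dd.items()):
            add(a, b, s)
            add(b, a, s)
        for a, b in sorted(network.pp):
            add(a, b, 1.0)
            add(b, a, 1.0)
        # association arcs are oriented disease -> protein (see
        # HeterogeneousNetwork.flow_network for why)
        self._assoc_arcs_by_protein: Dict[str, List[int]] = {}
        self._assoc_arcs_by_pair: Dict[Tuple[str, str], List[int]] = {}
        for d, p in sorted(network.dp):
            e1 = add(d, p, network.big_m)
            self._assoc_arcs_by_protein.setdefault(p, []).append(e1)
            self._assoc_arcs_by_pair[(d, p)] = [e1]

        self._sink_arc: Dict[str, int] = {}
        for p in network.proteins:
            edges.append((self._idx[p], self._sink))
            caps.append(0.0)
            self._arc_names.append((p, SINK))
            self._sink_arc[p] = len(edges) - 1

        self._graph = ig.Graph(self._sink + 1, edges, directed=True)
        self._base_caps = np.asarray(caps, dtype=float)

    # -- scoring ---------------------------------------------------------

    def _capacities(
        self,
        members: Iterable[str],
        holdout_proteins: Iterable[str],
        holdout_pairs: Iterable[Tuple[str, str]],
    ) -> Tuple[np.ndarray, List[int]]:
        caps = self._base_caps.copy()
        zero: List[int] = []
        for p in holdout_proteins:
            zero.extend(self._assoc_arcs_by_protein.get(p, ()))
        for pair in holdout_pairs:
            zero.extend(self._assoc_arcs_by_pair.get(pair, ()))
        if zero:
            caps[zero] = 0.0
        member_arcs = [
            self._sink_arc[p] for p in members if p in self._sink_arc
        ]
        if member_arcs:
            caps[member_arcs] = self.network.big_m
        return caps, member_arcs

    def flow_value(
        self,
        query: str,
        members: Iterable[str],
        holdout_proteins: Iterable[str] = (),
        holdout_pairs: Iterable[Tuple[str, str]] = (),
    ) -> float:
        """Max-flow value from ``query`` to a sink behind ``members``."""
        if query not in self._disease_set:
            raise KeyError(f"query {query!r} is not a disease node of the network")
        caps, member_arcs = self._capacities(members, holdout_proteins, holdout_pairs)
        if not member_arcs:
            return 0.0
        mf = self._graph.maxflow(self._idx[query], self._sink, caps.tolist())
        return float(mf.value)

    def flow_result(
        self,
        query: str,
        members: Iterable[str],
        holdout_proteins: Iterable[str] = (),
        holdout_pairs: Iterable[Tuple[str, str]] = (),
    ) -> FlowResult:
        """Like :meth:`flow_value` but returning the full arc-flow assignment.

        Used by the tests to verify feasibility of the engine's flows.
        """
        if query not in self._disease_set:
            raise KeyError(f"query {query!r} is not a disease node of the network")
        caps, member_arcs = self._capacities(members, holdout_proteins, holdout_pairs)
        if not member_arcs:
            return FlowResult(0.0, {}, query, SINK)
        mf = self._graph.maxflow(self._idx[query], self._sink, caps.tolist())
        arc_flow = {}
        for name, f, c in zip(self._arc_names, mf.flow, caps):
            if c > 0.0:
                arc_flow[name] = min(max(float(f), 0.0), float(c))
        return FlowResult(float(mf.value), arc_flow, query, SINK)

    def as_flow_network(
        self,
        members: Iterable[str],
        holdout_proteins: Iterable[str] = (),
        holdout_pairs: Iterable[Tuple[str, str]] = (),
    ) -> FlowNetwork:
        """Materialize the currently scored configuration as a FlowNetwork."""
        caps, _ = self._capacities(members, holdout_proteins, holdout_pairs)
        net = FlowNetwork(nodes=self._nodes + [SINK])
        for name, c in zip(self._arc_names, caps):
            if c > 0.0:
                net.add_arc(name[0], name[1], float(c))
        return net


def _denominator(
    complex_: ProteinComplex, n_present: int, policy: str
) -> int:
    if policy == "annotated":
        return complex_.size
    if policy == "present":
        return max(n_present, 1)
    raise ValueError(f"unknown denominator policy {policy!r}")


def compute_mif(
    network: HeterogeneousNetwork,
    query: str,
    complex_: ProteinComplex,
    denominator: str = "annotated",
    engine: Optional[MIFEngine] = None,
    method: str = "engine",
) -> ComplexScore:
    """MIF of one complex for one query disease.

    ``method="engine"`` uses the shared igraph engine (building one if
    none is supplied); ``method="push_relabel"`` attaches an explicit sink
    and runs the package's own solver -- slower, used for cross-checks.
    The input network is never modified.
    """
    if query not in set(network.diseases):
        raise KeyError(f"query {query!r} is not a disease node of the network")
    present = set(complex_.members) & set(network.proteins)
    if method == "engine":
        eng = engine if engine is not None else MIFEngine(network)
        value = eng.flow_value(query, complex_.members)
    elif method == "push_relabel":
        fn = attach_complex_sink(network, complex_)
        value = 0.0 if not present else max_flow(fn, query, SINK).value
    else:
        raise ValueError(f"unknown method {method!r}")
    denom = _denominator(complex_, len(present), denominator)
    return ComplexScore(
        complex_id=complex_.complex_id,
        mif=value / denom,
        n_members=complex_.size,
        n_members_in_network=len(present),
    )


def rank_complexes(
    network: HeterogeneousNetwork,
    query: str,
    complexes: Sequence[ProteinComplex],
    denominator: str = "annotated",
    engine: Optional[MIFEngine] = None,
) -> List[ComplexScore]:
    """Score every candidate complex and rank by MIF (descending).

    Ties receive fractional (mean-of-positions) ranks.  The returned list
    is sorted by rank, then complex id for a deterministic order.
    """
    if not complexes:
        raise ValueError("complexes must be nonempty")
    eng = engine if engine is not None else MIFEngine(network)
    scores = [
        compute_mif(network, query, c, denominator=denominator, engine=eng)
        for c in complexes
    ]
    mifs = np.array([s.mif for s in scores])
    ranks = rankdata(-mifs, method="average")
    ranked = [
        ComplexScore(
            complex_id=s.complex_id,
            mif=s.mif,
            n_members=s.n_members,
            n_members_in_network=s.n_members_in_network,
            rank=float(r),
        )
        for s, r in zip(scores, ranks)
    ]
    ranked.sort(key=lambda s: (s.rank, s.complex_id))
    if mifs.max(initial=0.0) == 0.0:
        logger.warning(
            "all candidate MIFs are 0 for query %s; ranking is fully tied", query
        )
    return ranked


def write_ranking(scores: Sequence[ComplexScore], path, query: str) -> None:
    """Write a ranking as TSV (query, complex, mif, rank, member counts)."""
    with open(path, "w") as fh:
        fh.write(
            "query_disease\tcomplex_id\tmif\trank\tn_members\tn_members_in_network\n"
        )
        for s in scores:
            fh.write(
                f"{query}\t{s.complex_id}\t{s.mif:.10g}\t{s.rank:g}\t"
                f"{s.n_members}\t{s.n_members_in_network}\n"
            )
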