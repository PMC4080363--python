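"""Assembly of the heterogeneous disease-protein flow network.

The network joins three data layers over two node classes:

* disease-disease edges weighted by phenotypic similarity in [0, 1],
  kept only when the similarity reaches the noise-filter threshold
  ``alpha`` (default 0.1);
* protein-protein interaction edges, each with capacity 1;
* disease-protein association edges, conceptually of infinite capacity.

"Infinite" is materialized as a big-M constant equal to the sum of all
finite capacities in the network plus one, so that association (and
complex-sink) arcs are never flow-limiting relative to the finite part of
the network while every max-flow value stays finite.  Every undirected
edge becomes two antiparallel arcs of equal capacity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Set, Tuple

from .flow import FlowNetwork

logger = logging.getLogger("maxcom")

Pair = Tuple[str, str]

DISEASE = "disease"
PROTEIN = "protein"

#: default sink node id used when scoring a complex
SINK = "__sink__"


def _canon(a: str, b: str) -> Pair:
    """Canonical (sorted) form of an unordered id pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SimilarityTable:
    """Symmetric disease-disease phenotypic similarities in [0, 1].

    Only nonzero entries are stored; absent pairs have similarity 0.
    ``diseases`` is the full disease universe (a disease may appear with
    no nonzero similarity to anything).
    """

    entries: Mapping[Pair, float]
    diseases: FrozenSet[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        universe = set(self.diseases)
        for (a, b), s in self.entries.items():
            if a == b:
                raise ValueError(f"self-similarity for disease {a!r} is not allowed")
            if (a, b) != _canon(a, b):
                raise ValueError(f"similarity pair {(a, b)!r} is not in canonical order")
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"similarity for pair {(a, b)!r} is {s!r}, outside [0, 1]"
                )
            universe.add(a)
            universe.add(b)
        object.__setattr__(self, "diseases", frozenset(universe))

    @classmethod
    def from_records(
        cls,
        records: Iterable[Tuple[str, str, float]],
        diseases: Iterable[str] = (),
    ) -> "SimilarityTable":
        """Build from (a, b, similarity) triples, merging symmetric duplicates."""
        entries: Dict[Pair, float] = {}
        for a, b, s in records:
            key = _canon(str(a), str(b))
            s = float(s)
            if key in entries and abs(entries[key] - s) > 1e-12:
                raise ValueError(
                    f"conflicting similarities for pair {key!r}: "
                    f"{entries[key]!r} vs {s!r}"
                )
            entries[key] = s
        return cls(entries=entries, diseases=frozenset(diseases))

    def __len__(self) -> int:
        return len(self.entries)

    def mean_similarity(self, include_zeros: bool = False) -> float:
        """Mean pairwise similarity, optionally counting absent pairs as 0."""
        if not self.entries and not include_zeros:
            return 0.0
        total = sum(self.entries.values())
        if include_zeros:
            n = len(self.diseases)
            n_pairs = n * (n - 1) // 2
            return total / n_pairs if n_pairs else 0.0
        return total / len(self.entries)


@dataclass(frozen=True)
class PPIEdgeList:
    """Undirected protein-protein interaction edges (no self-interactions)."""

    edges: FrozenSet[Pair]
    proteins: FrozenSet[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        universe = set(self.proteins)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-interaction for protein {a!r} is not allowed")
            if (a, b) != _canon(a, b):
                raise ValueError(f"PPI pair {(a, b)!r} is not in canonical order")
            universe.add(a)
            universe.add(b)
        object.__setattr__(self, "proteins", frozenset(universe))

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, str]], proteins: Iterable[str] = ()
    ) -> "PPIEdgeList":
        edges = set()
        for a, b in records:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-interaction for protein {a!r} is not allowed")
            edges.add(_canon(a, b))
        return cls(edges=frozenset(edges), proteins=frozenset(proteins))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class AssociationList:
    """Known disease-protein associations as (disease_id, protein_id) pairs."""

    pairs: FrozenSet[Pair]

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, str]]) -> "AssociationList":
        return cls(pairs=frozenset((str(d), str(p)) for d, p in records))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def diseases(self) -> Set[str]:
        return {d for d, _ in self.pairs}

    @property
    def proteins(self) -> Set[str]:
        return {p for _, p in self.pairs}


@dataclass(frozen=True)
class ProteinComplex:
    """A candidate protein complex: identifier, name, member protein set."""

    complex_id: str
    members: FrozenSet[str]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex {self.complex_id!r} has no members")
        object.__setattr__(self, "members", frozenset(str(p) for p in self.members))

    @property
    def size(self) -> int:
        return len(self.members)


def compute_big_m(finite_capacity_total: float) -> float:
    """Finite stand-in for an infinite capacity.

    One more than the total finite capacity in the network, so a big-M arc
    can never be the binding constraint of any cut that also contains a
    finite alternative.
    """
    if finite_capacity_total < 0:
        raise ValueError("finite capacity total must be >= 0")
    return float(finite_capacity_total) + 1.0


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Typed disease/protein flow network plus build metadata.

    Edges are stored by class on canonical unordered pairs:

    * ``dd`` -- disease pair -> retained similarity (all >= alpha, > 0)
    * ``pp`` -- protein interaction pairs (capacity 1 each)
    * ``dp`` -- (disease, protein) association pairs (capacity big_m)
    """

    diseases: Tuple[str, ...]
    proteins: Tuple[str, ...]
    dd: Mapping[Pair, float]
    pp: FrozenSet[Pair]
    dp: FrozenSet[Pair]
    alpha: float
    big_m: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    # -- structure -------------------------------------------------------

    @property
    def node_class(self) -> Dict[str, str]:
        out = {d: DISEASE for d in self.diseases}
        out.update({p: PROTEIN for p in self.proteins})
        return out

    @property
    def n_edges(self) -> int:
        return len(self.dd) + len(self.pp) + len(self.dp)

    def edge_counts(self) -> Dict[str, int]:
        return {"dd": len(self.dd), "pp": len(self.pp), "dp": len(self.dp)}

    def finite_capacity_total(self) -> float:
        """Sum of all finite (non-big-M) arc capacities, counting both arcs."""
        return 2.0 * (sum(self.dd.values()) + float(len(self.pp)))

    @cached_property
    def flow_network(self) -> FlowNetwork:
        """Build the arc-level flow network.

        Similarity and interaction edges are undirected (antiparallel arc
        pairs); association arcs are oriented disease -> protein.  An
        unoriented big-M association arc would let flow re-enter the
        disease layer through any annotated protein, turning every such
        protein into an unlimited absorber for every query; orienting the
        arcs source-to-sink keeps big-M capacity usable only on the
        disease-to-complex direction the score is defined over.
        """
        net = FlowNetwork(nodes=list(self.diseases) + list(self.proteins))
        for (a, b), s in self.dd.items():
            net.add_undirected_edge(a, b, s)
        for a, b in self.pp:
            net.add_undirected_edge(a, b, 1.0)
        for d, p in self.dp:
            net.add_arc(d, p, self.big_m)
        return net

    def digest(self) -> str:
        """Deterministic content hash of the built network."""
        h = hashlib.sha256()
        h.update(f"alpha={self.alpha!r};big_m={self.big_m!r};".encode())
        for d in self.diseases:
            h.update(f"D:{d};".encode())
        for p in self.proteins:
            h.update(f"P:{p};".encode())
        for (a, b), s in sorted(self.dd.items()):
            h.update(f"dd:{a},{b},{s:.17g};".encode())
        for a, b in sorted(self.pp):
            h.update(f"pp:{a},{b};".encode())
        for d, p in sorted(self.dp):
            h.update(f"dp:{d},{p};".encode())
        return h.hexdigest()

    # -- derived networks ------------------------------------------------

    def drop_associations_touching(self, proteins: Iterable[str]) -> "HeterogeneousNetwork":
        """Copy with every association arc incident to ``proteins`` removed.

        This is the leave-one-out holdout: big_m is left unchanged (it only
        ever needs to exceed the finite capacity total, which does not grow).
        """
        drop = set(proteins)
        kept = frozenset((d, p) for d, p in self.dp if p not in drop)
        return replace(self, dp=kept)

    def drop_association_pairs(self, pairs: Iterable[Pair]) -> "HeterogeneousNetwork":
        drop = set(pairs)
        return replace(self, dp=frozenset(p for p in self.dp if p not in drop))


def build_network(
    sim: SimilarityTable,
    ppi: PPIEdgeList,
    assoc: AssociationList,
    alpha: float = 0.1,
) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from the three input layers.

    Disease pairs with nonzero similarity >= ``alpha`` become edges with
    capacity equal to the similarity; PPI edges get capacity 1;
    associations get capacity big_m (computed after filtering).
    Associations whose ids are unknown to the similarity/PPI universes are
    dropped with a logged warning.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha!r}")
    if len(sim.diseases) == 0:
        raise ValueError("similarity layer is empty: no diseases")
    if len(ppi.proteins) == 0:
        raise ValueError("PPI layer is empty: no proteins")
    if len(assoc) == 0:
        raise ValueError("association layer is empty")

    diseases = tuple(sorted(sim.diseases))
    proteins = tuple(sorted(ppi.proteins))
    disease_set, protein_set = set(diseases), set(proteins)

    # zero-similarity pairs never become arcs regardless of alpha
    dd = {pair: s for pair, s in sim.entries.items() if s > 0.0 and s >= alpha}

    kept = []
    dropped = 0
    for d, p in assoc.pairs:
        if d in disease_set and p in protein_set:
            kept.append((d, p))
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "dropped %d association(s) with ids unknown to the disease/protein universes",
            dropped,
        )

    finite_total = 2.0 * (sum(dd.values()) + float(len(ppi.edges)))
    big_m = compute_big_m(finite_total)

    provenance = {
        "n_diseases": len(diseases),
        "n_proteins": len(proteins),
        "n_similarity_pairs_input": len(sim),
        "n_dd_edges": len(dd),
        "n_pp_edges": len(ppi.edges),
        "n_dp_edges": len(kept),
        "n_assoc_dropped": dropped,
        "alpha": alpha,
        "mean_similarity_nonzero": sim.mean_similarity(include_zeros=False),
        "mean_similarity_all_pairs": sim.mean_similarity(include_zeros=True),
    }
    return HeterogeneousNetwork(
        diseases=diseases,
        proteins=proteins,
        dd=dd,
        pp=frozenset(ppi.edges),
        dp=frozenset(kept),
        alpha=alpha,
        big_m=big_m,
        provenance=provenance,
    )


def attach_complex_sink(
    network: HeterogeneousNetwork,
    complex_: ProteinComplex,
    sink: str = SINK,
) -> FlowNetwork:
    """Return a copy of the flow network with a sink behind the complex.

    One arc ``member -> sink`` of capacity big_m is added for every member
    present in the network.  The input network is not modified; if no
    member is present the sink is isolated (every flow to it is 0) and a
    warning is logged.
    """
    fn = network.flow_network.copy()
    if sink in fn:
        raise ValueError(f"sink id {sink!r} collides with an existing node")
    fn.add_node(sink)
    present = sorted(set(complex_.members) & set(network.proteins))
    if not present:
        logger.warning(
            "complex %s has no member present in the network; attaching isolated sink",
            complex_.complex_id,
        )
    for p in present:
        fn.add_arc(p, sink, network.big_m)
    fn.sink = sink
    return fn


def detach_sink(flow_network: FlowNetwork, sink: str = SINK) -> FlowNetwork:
    """Inverse of :func:`attach_complex_sink` (removes the sink node and its arcs)."""
    out = FlowNetwork(nodes=[u for u in flow_network.nodes if u != sink])
    for (u, v), c in flow_network.arcs.items():
        if sink not in (u, v):
            out.add_arc(u, v, c)
    return out
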