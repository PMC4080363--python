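"""Network-robustness perturbations: edge deletion, addition, degree-preserving shuffle.

These operations probe how much of the prioritization signal survives
structural noise.  Random deletion/addition of a small fraction of edges
models false-negative/false-positive interactions and similarities; a
degree-preserving double-edge-swap shuffle destroys the meaning of every
edge while keeping each node's degree, and should reduce performance to
chance if the method exploits edge semantics rather than degree alone.

All perturbations are class-aware by default: the three edge classes
(disease-disease, protein-protein, disease-protein) are perturbed
proportionally and never mixed, so a similarity edge can never become an
association edge.  Node sets are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from .network import HeterogeneousNetwork, Pair, compute_big_m, _canon

_CLASSES = ("dd", "pp", "dp")


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative description of one perturbation."""

    kind: str  # delete | add | shuffle
    fraction: float = 0.1
    n_swap_multiplier: int = 10
    seed: int = 0
    class_policy: str = "stratified"  # stratified | global

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "add", "shuffle"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not (0.0 <= self.fraction <= 1.0) and self.kind == "delete":
            raise ValueError("fraction must be in [0, 1]")
        if self.fraction < 0.0:
            raise ValueError("fraction must be >= 0")
        if self.n_swap_multiplier < 1:
            raise ValueError("n_swap_multiplier must be >= 1")
        if self.class_policy not in ("stratified", "global"):
            raise ValueError(f"unknown class policy {self.class_policy!r}")


def apply_perturbation(
    network: HeterogeneousNetwork, spec: PerturbationSpec
) -> HeterogeneousNetwork:
    if spec.kind == "delete":
        return delete_random_edges(
            network, spec.fraction, spec.seed, policy=spec.class_policy
        )
    if spec.kind == "add":
        return add_random_edges(
            network, spec.fraction, spec.seed, policy=spec.class_policy
        )
    return degree_preserving_shuffle(network, spec.n_swap_multiplier, spec.seed)


def _class_sizes(net: HeterogeneousNetwork) -> Dict[str, int]:
    return {"dd": len(net.dd), "pp": len(net.pp), "dp": len(net.dp)}


def _allocate(total_k: int, sizes: Dict[str, int], caps: Dict[str, int]) -> Dict[str, int]:
    """Largest-remainder allocation of ``total_k`` across classes.

    Proportional to ``sizes``, never exceeding per-class ``caps``, summing
    exactly to ``total_k`` (assuming sum(caps) >= total_k).
    """
    total = sum(sizes.values())
    if total == 0:
        return {c: 0 for c in _CLASSES}
    quota = {c: total_k * sizes[c] / total for c in _CLASSES}
    alloc = {c: min(int(quota[c]), caps[c]) for c in _CLASSES}
    remainders = sorted(
        _CLASSES, key=lambda c: (quota[c] - int(quota[c])), reverse=True
    )
    i = 0
    while sum(alloc.values()) < total_k:
        c = remainders[i % len(_CLASSES)]
        if alloc[c] < caps[c]:
            alloc[c] += 1
        i += 1
        if i > 10 * len(_CLASSES) and all(alloc[c] >= caps[c] for c in _CLASSES):
            raise ValueError("not enough room to allocate perturbation quota")
    return alloc


def delete_random_edges(
    network: HeterogeneousNetwork,
    fraction: float,
    seed: int,
    policy: str = "stratified",
) -> HeterogeneousNetwork:
    """Remove round(fraction * E) undirected edges uniformly at random.

    ``stratified`` removes proportionally within each edge class;
    ``global`` samples over the pooled edge set.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    e_total = network.n_edges
    k = int(round(fraction * e_total))
    sizes = _class_sizes(network)
    if policy == "stratified":
        alloc = _allocate(k, sizes, caps=sizes)
    elif policy == "global":
        pooled = (
            [("dd", e) for e in sorted(network.dd)]
            + [("pp", e) for e in sorted(network.pp)]
            + [("dp", e) for e in sorted(network.dp)]
        )
        picks = rng.choice(len(pooled), size=k, replace=False)
        chosen = [pooled[int(i)] for i in picks]
        alloc = None
    else:
        raise ValueError(f"unknown class policy {policy!r}")

    if alloc is not None:
        chosen = []
        for cls in _CLASSES:
            edges = sorted(network.dd) if cls == "dd" else sorted(
                network.pp if cls == "pp" else network.dp
            )
            if alloc[cls] == 0:
                continue
            picks = rng.choice(len(edges), size=alloc[cls], replace=False)
            chosen.extend((cls, edges[int(i)]) for i in picks)

    drop = {"dd": set(), "pp": set(), "dp": set()}
    for cls, e in chosen:
        drop[cls].add(e)
    new = replace(
        network,
        dd={e: s for e, s in network.dd.items() if e not in drop["dd"]},
        pp=frozenset(e for e in network.pp if e not in drop["pp"]),
        dp=frozenset(e for e in network.dp if e not in drop["dp"]),
        provenance={**network.provenance, "perturbation": f"delete {fraction}"},
    )
    return new


def _sample_absent_pairs(
    rng: np.random.Generator,
    left: Sequence[str],
    right: Sequence[str],
    existing: Set[Pair],
    k: int,
    bipartite: bool,
) -> List[Pair]:
    """Uniformly sample ``k`` distinct absent pairs (rejection sampling)."""
    if bipartite:
        n_possible = len(left) * len(right)
    else:
        n_possible = len(left) * (len(left) - 1) // 2
    if n_possible - len(existing) < k:
        raise ValueError(
            f"not enough absent pairs: need {k}, have {n_possible - len(existing)}"
        )
    out: Set[Pair] = set()
    attempts = 0
    max_attempts = 1000 * max(k, 1) + 10000
    while len(out) < k:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("rejection sampling for absent pairs did not converge")
        if bipartite:
            a = left[int(rng.integers(len(left)))]
            b = right[int(rng.integers(len(right)))]
            pair = (a, b)
        else:
            i = int(rng.integers(len(left)))
            j = int(rng.integers(len(left)))
            if i == j:
                continue
            pair = _canon(left[i], left[j])
        if pair in existing or pair in out:
            continue
        out.add(pair)
    return sorted(out)


def add_random_edges(
    network: HeterogeneousNetwork,
    fraction: float,
    seed: int,
    policy: str = "stratified",
) -> HeterogeneousNetwork:
    """Add round(fraction * E) new edges between currently-unlinked pairs.

    New protein-protein edges get capacity 1; new disease-disease edges
    draw their similarity from the empirical retained-similarity
    distribution; new associations get big_m (big_m is recomputed after
    the addition so it still dominates the finite capacity total).
    ``stratified`` adds within classes proportionally to existing class
    sizes; ``global`` pools all classes when allocating.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    rng = np.random.default_rng(seed)
    e_total = network.n_edges
    k = int(round(fraction * e_total))
    sizes = _class_sizes(network)
    room = {
        "dd": len(network.diseases) * (len(network.diseases) - 1) // 2 - sizes["dd"],
        "pp": len(network.proteins) * (len(network.proteins) - 1) // 2 - sizes["pp"],
        "dp": len(network.diseases) * len(network.proteins) - sizes["dp"],
    }
    alloc = _allocate(k, sizes, caps=room)

    diseases = list(network.diseases)
    proteins = list(network.proteins)

    new_dd = dict(network.dd)
    if alloc["dd"]:
        pairs = _sample_absent_pairs(
            rng, diseases, diseases, set(network.dd), alloc["dd"], bipartite=False
        )
        sims = sorted(network.dd.values())
        for pair in pairs:
            if sims:
                new_dd[pair] = float(sims[int(rng.integers(len(sims)))])
            else:
                new_dd[pair] = float(rng.uniform(max(network.alpha, 1e-6), 1.0))

    new_pp = set(network.pp)
    if alloc["pp"]:
        new_pp.update(
            _sample_absent_pairs(
                rng, proteins, proteins, set(network.pp), alloc["pp"], bipartite=False
            )
        )

    new_dp = set(network.dp)
    if alloc["dp"]:
        new_dp.update(
            _sample_absent_pairs(
                rng, diseases, proteins, set(network.dp), alloc["dp"], bipartite=True
            )
        )

    finite_total = 2.0 * (sum(new_dd.values()) + float(len(new_pp)))
    return replace(
        network,
        dd=new_dd,
        pp=frozenset(new_pp),
        dp=frozenset(new_dp),
        big_m=compute_big_m(finite_total),
        provenance={**network.provenance, "perturbation": f"add {fraction}"},
    )


def _shuffle_class(
    rng: np.random.Generator,
    edges: List[Tuple[Pair, float]],
    n_attempts: int,
    bipartite: bool,
) -> List[Tuple[Pair, float]]:
    """Double-edge swaps preserving every endpoint's within-class degree.

    Capacities stay attached to their edge slot, so the capacity multiset
    is preserved exactly.  For the bipartite association class the swap
    exchanges protein partners between two (disease, protein) edges.
    """
    if len(edges) < 2:
        return edges
    current = {e for e, _ in edges}
    slots = [list(e) for e, _ in edges]
    caps = [c for _, c in edges]
    m = len(slots)
    for _ in range(n_attempts):
        i = int(rng.integers(m))
        j = int(rng.integers(m))
        if i == j:
            continue
        a, b = slots[i]
        c, d = slots[j]
        if bipartite:
            # (disease a, protein b), (disease c, protein d) -> (a,d),(c,b)
            e1, e2 = (a, d), (c, b)
            if a == c or b == d:
                continue
        else:
            if rng.integers(2):
                c, d = d, c
            if a == d or c == b:
                continue
            e1, e2 = _canon(a, d), _canon(c, b)
        if e1 in current or e2 in current or e1 == e2:
            continue
        current.discard(tuple(slots[i]) if bipartite else _canon(*slots[i]))
        current.discard(tuple(slots[j]) if bipartite else _canon(*slots[j]))
        current.add(e1)
        current.add(e2)
        slots[i] = list(e1)
        slots[j] = list(e2)
    return [((s[0], s[1]), cap) for s, cap in zip(slots, caps)]


def degree_preserving_shuffle(
    network: HeterogeneousNetwork,
    n_swap_multiplier: int = 10,
    seed: int = 0,
) -> HeterogeneousNetwork:
    """Shuffle edges within each class, preserving per-class degree sequences.

    Performs ``n_swap_multiplier * E_class`` attempted double-edge swaps
    per class.  Edge semantics (which disease is similar to which, which
    protein interacts with which) are destroyed; degrees, class sizes and
    the capacity multiset per class are preserved exactly.
    """
    if n_swap_multiplier < 1:
        raise ValueError("n_swap_multiplier must be >= 1")
    rng = np.random.default_rng(seed)

    dd_edges = sorted(network.dd.items())
    dd_shuffled = _shuffle_class(
        rng, [(e, s) for e, s in dd_edges], n_swap_multiplier * len(dd_edges), False
    )

    pp_edges = sorted(network.pp)
    pp_shuffled = _shuffle_class(
        rng, [(e, 1.0) for e in pp_edges], n_swap_multiplier * len(pp_edges), False
    )

    dp_edges = sorted(network.dp)
    dp_shuffled = _shuffle_class(
        rng,
        [(e, network.big_m) for e in dp_edges],
        n_swap_multiplier * len(dp_edges),
        True,
    )

    return replace(
        network,
        dd={e: s for e, s in dd_shuffled},
        pp=frozenset(e for e, _ in pp_shuffled),
        dp=frozenset(e for e, _ in dp_shuffled),
        provenance={
            **network.provenance,
            "perturbation": f"shuffle x{n_swap_multiplier}",
        },
    )
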