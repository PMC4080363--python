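"""How much prioritization signal survives structural noise in the network?

Random deletion or addition of 10% of edges models interaction noise; a
degree-preserving shuffle keeps every node's connectivity but destroys
what each edge means, so it should push performance toward chance if the
method uses edge semantics rather than degree alone.

Runs on a subset of test complexes to keep the demo quick; drop `limit`
for the full experiment.
"""

import time

from maxcom import (
    BenchmarkSpec,
    build_network,
    compute_metrics,
    degree_preserving_shuffle,
    delete_random_edges,
    add_random_edges,
    generate_benchmark,
    loocv,
)

sim, ppi, assoc, complexes, truth = generate_benchmark(BenchmarkSpec())
network = build_network(sim, ppi, assoc, alpha=0.1)

variants = {
    "intact": network,
    "10% edges deleted": delete_random_edges(network, 0.1, seed=7),
    "10% edges added": add_random_edges(network, 0.1, seed=7),
    "degree-preserving shuffle": degree_preserving_shuffle(network, 10, seed=7),
}

print(f"{'network':28} {'TOP':>7} {'MRR':>7} {'AUC':>7}")
for name, net in variants.items():
    t0 = time.perf_counter()
    runs = loocv(net, complexes, assoc, n_random_controls=99, seed=0, limit=20)
    m = compute_metrics(runs)
    print(f"{name:28} {m.top:7.3f} {m.mrr:7.3f} {m.auc:7.3f}   ({time.perf_counter()-t0:.0f}s)")

print(
    "\nModerate random noise barely moves the AUC, but the shuffle collapses\n"
    "it toward 0.5: the ranking signal lives in which diseases, genes and\n"
    "interactions are connected, not in the degree distribution."
)
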