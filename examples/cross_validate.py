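"""Leave-one-out cross-validation against random control complexes.

Each disease-associated complex in turn becomes the hidden positive: all
of its association arcs are removed from the network, and it is re-ranked
by MIF against 99 size-matched random complexes.  TOP is the fraction of
runs where the positive comes back first, MRR the mean relative rank, and
the rank-ROC AUC summarizes the overall separation from the controls.
"""

import time

from maxcom import BenchmarkSpec, build_network, compute_metrics, generate_benchmark, loocv

sim, ppi, assoc, complexes, truth = generate_benchmark(BenchmarkSpec())
network = build_network(sim, ppi, assoc, alpha=0.1)

t0 = time.perf_counter()
runs = loocv(network, complexes, assoc, control_kind="random", n_random_controls=99, seed=0)
metrics = compute_metrics(runs)

print(f"{metrics.n_runs} leave-one-out runs in {time.perf_counter() - t0:.1f}s")
print(f"  TOP (strict rank-1 rate) : {metrics.top:.4f}")
print(f"  MRR (mean rank ratio)    : {metrics.mrr:.4f}")
print(f"  rank-ROC AUC             : {metrics.auc:.4f}")

print(
    "\nA high AUC with a low MRR means held-out positives consistently rank\n"
    "near the top of their 100-candidate lists.  The strict TOP rate is\n"
    "depressed at this benchmark scale: a random control that happens to\n"
    "contain the query's one remaining annotated protein inherits its\n"
    "infinite-capacity arc and jumps ahead of the positive."
)
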