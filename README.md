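# maxcom

Prioritization of disease-related protein complexes by maximum
information flow through a heterogeneous disease–protein network.

## The problem

Diseases are usually studied gene by gene, but the functional units that
break in disease are often whole protein complexes.  Given a query
disease, which of the hundreds of catalogued complexes is most likely
involved?  `maxcom` answers this by network optimization over three data
layers:

* **disease–disease** edges weighted by phenotypic similarity in [0, 1],
  filtered at a noise threshold α (default 0.1);
* **protein–protein** interaction edges with capacity 1;
* **disease–protein** association edges with "infinite" capacity,
  materialized as a big-M constant (sum of all finite capacities + 1)
  and oriented disease → protein.

For a candidate complex *C(i)* a sink node is attached behind its
members (one big-M arc per member), and the score is the **maximum
information flow** from the query disease *q* to that sink:

```
MIF(i) = f*(q → sink_i) / |C(i)|,
f*  =  max Σ_v f(q, v)   s.t.   0 ≤ f(v,w) ≤ cap(v,w),  flow conserved
```

where |C(i)| is the full annotated member count.  Candidates are ranked
by MIF; ties receive fractional (mean) ranks.  A strongly implicated
complex sits inside the query's "disease module" — close, in capacity
terms, to the genes of phenotypically similar diseases — and drains far
more flow than an arbitrary protein set of the same size.

The package ships the complete evaluation harness from the underlying
method: leave-one-out cross-validation against size-matched random
controls or against the remaining catalogue (TOP / mean-rank-ratio /
rank-ROC-AUC), network-robustness perturbations (random edge deletion
and addition, degree-preserving shuffle), an α-threshold sweep, and a
synthetic benchmark generator so every stage is testable without any
external download.

## Worked example

```python
from maxcom import BenchmarkSpec, generate_benchmark, build_network, rank_complexes

sim, ppi, assoc, complexes, truth = generate_benchmark(BenchmarkSpec())
network = build_network(sim, ppi, assoc, alpha=0.1)
query, planted = sorted(truth.pairs)[0]
for s in rank_complexes(network, query, complexes)[:5]:
    print(f"{s.rank:5.1f}  {s.complex_id}  MIF={s.mif:.3f}")
```

prints (seed 42):

```
  1.0  CPX040  MIF=1458.476
  2.0  CPX020  MIF=1193.299
  3.0  CPX030  MIF=1097.509
  4.0  CPX000  MIF=598.641
  5.0  CPX010  MIF=9.956
```

The planted positive `CPX040` ranks first: the query's association arcs
inject big-M capacity straight into its members, while unrelated decoy
complexes receive only what leaks across weak similarity edges.  In the
leave-one-out setting (run `examples/cross_validate.py`) those arcs are
hidden, and the held-out positive must be re-discovered from the
similarity layer and module structure alone — on the default benchmark
this yields a rank-ROC AUC of ≈ 0.94 with mean rank ratio ≈ 0.06
against 99 random controls per run.

Each script in `examples/` demonstrates one capability end to end:
benchmark generation, single-disease ranking, cross-validation,
perturbation robustness, and the α sweep.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic benchmark from the given seed, builds the
network, runs the full leave-one-out cross-validation against 99 random
controls per test complex, and prints the TOP / MRR / AUC summary to
stderr; the JSON output holds the per-target results (this artifact
defines no numeric targets, so the object is empty).

See `docs/methods.md` for the model assumptions, the synthetic world's
design and its limitations.
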