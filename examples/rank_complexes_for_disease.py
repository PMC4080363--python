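"""Rank all candidate complexes for one query disease by information flow.

The score of a complex is the maximum flow the query disease can push
through the heterogeneous network into a sink attached behind the
complex's members, divided by the complex size.  Larger MIF = stronger
predicted disease-complex association.
"""

from maxcom import BenchmarkSpec, build_network, generate_benchmark, rank_complexes

sim, ppi, assoc, complexes, truth = generate_benchmark(BenchmarkSpec())
network = build_network(sim, ppi, assoc, alpha=0.1)

# pick a disease with a known (planted) complex so we can check the answer
query, true_complex = sorted(truth.pairs)[0]
print(f"query disease: {query}   (planted truth: {true_complex})\n")

ranking = rank_complexes(network, query, complexes)
print(f"{'rank':>5} {'complex':10} {'MIF':>10} {'members':>8}")
for score in ranking[:10]:
    marker = "  <-- planted positive" if score.complex_id == true_complex else ""
    print(
        f"{score.rank:5.1f} {score.complex_id:10} {score.mif:10.3f} "
        f"{score.n_members:8d}{marker}"
    )

print(
    "\nThe planted complex carries the query's association arcs, so flow\n"
    "reaches its sink at big-M capacity and it ranks at the very top;\n"
    "decoy complexes far from the disease module receive almost no flow."
)
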