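"""Generate the default synthetic benchmark and summarize its structure.

The generator emulates the three data layers the prioritization method
consumes -- a family-structured disease phenotypic similarity matrix, a
sparse modular interactome with planted protein complexes, and a sparse
disease-protein association catalogue -- plus the ground-truth
disease-complex pairs everything else is scored against.
"""

from pathlib import Path

from maxcom import BenchmarkSpec, generate_benchmark, summarize_benchmark, write_benchmark

spec = BenchmarkSpec()  # 200 diseases / 10 families, 1,000 proteins, 60 complexes
outputs = generate_benchmark(spec)
sim, ppi, assoc, complexes, truth = outputs

print("benchmark summary (seed %d):" % spec.seed)
for key, value in summarize_benchmark(*outputs).items():
    print(f"  {key:32s} {value:.4g}" if isinstance(value, float) else f"  {key:32s} {value}")

out_dir = Path("scratch/benchmark")
paths = write_benchmark(outputs, out_dir)
print(f"\nwrote plain-text input files to {out_dir}/:")
for name, path in paths.items():
    print(f"  {name:14s} {path}")

print(
    "\nThe within-complex interaction density is far above the background\n"
    "density: complexes are dense local neighbourhoods of the interactome,\n"
    "which is the structural signal the flow-based ranking exploits."
)
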