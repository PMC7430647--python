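"""Simulate a wild-type extracellular RNA library and classify its fragments.

Builds the toy reference, draws 20 000 library molecules under the wild-type
processing model (most tRNAs cleaved in the anticodon loop), runs the full
classification pipeline, and prints the dataset-level metrics.
"""

from exofrag import SimConfig, build_toy_reference, run_pipeline, simulate_library
from exofrag.report import top_table

toy = build_toy_reference(seed=1)
sim = simulate_library(SimConfig(seed=1, n_reads=20_000), toy.annotation, toy.genome)
out = run_pipeline(sim.records, toy.annotation, toy.genome)

s = out.summary
print(f"mapped primary alignments : {s.n_mapped_primary}")
print(f"qualified tRNA reads      : {s.n_qualified}")
print(f"tRNA halves               : {s.n_halves} ({100 * s.half_fraction:.1f}% of mapped)")
print(f"5' / 3' split             : {100 * s.split5:.1f}% / {100 * s.split3:.1f}%")
print("most abundant half species (% of all halves):")
for row in top_table(out.calls, k=3):
    print(f"  {row['family']:<8} {row['half']}  {row['pct_of_halves']:5.1f}%")

# The half fraction tells you how much of the mapped library is anticodon-loop
# cleavage product; the split shows both halves are well represented when
# library ends are healed; the top table mirrors which isoacceptors dominate.
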