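"""Compare nontemplated CCA-tail status between wild-type and nuclease-null
libraries.

In the wild type, reads reaching the annotated tRNA 3' end mostly carry a
single nontemplated C (the CCA tail cleaved between its two cytidines); in
the mutant the intact CCA dominates, showing that tail trimming depends on
the extracellular nuclease.
"""

from exofrag import SimConfig, build_toy_reference, run_pipeline, simulate_library

toy = build_toy_reference(seed=1)
for genotype in ("WT", "mutant"):
    sim = simulate_library(
        SimConfig(seed=2, n_reads=10_000, genotype=genotype), toy.annotation, toy.genome
    )
    table = run_pipeline(sim.records, toy.annotation, toy.genome).summary.tail_table
    shares = ", ".join(
        f"{k}: {100 * v:.1f}%" for k, v in table["fractions"].items()
    )
    print(f"{genotype:>6}  (n_tailed={table['n_tailed']})  {shares}")
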