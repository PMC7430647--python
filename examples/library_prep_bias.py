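"""Show how skipping PNK end healing suppresses 3' tRNA halves.

Ribonuclease cleavage leaves a 2'-3' cyclic phosphate and a 5' hydroxyl,
both unligatable.  A 5' half carries one such end, a 3' half (whose CCA tail
was also trimmed) two, so omitting PNK treatment depletes 3' halves more.
The two runs below share the same seed, hence the same molecules: only the
cloning step differs.
"""

from exofrag import SimConfig, build_toy_reference, run_pipeline, simulate_library

toy = build_toy_reference(seed=1)
for pnk in (True, False):
    cfg = SimConfig(seed=4, n_reads=10_000, pnk_treated=pnk)
    sim = simulate_library(cfg, toy.annotation, toy.genome)
    s = run_pipeline(sim.records, toy.annotation, toy.genome).summary
    print(
        f"PNK {'on ' if pnk else 'off'}: mapped={s.n_mapped_primary:>6} "
        f"halves={s.n_halves:>5}  split 5'/3' = "
        f"{100 * s.split5:.1f}% / {100 * s.split3:.1f}%"
    )
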