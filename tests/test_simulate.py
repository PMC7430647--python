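import pytest

from exofrag.annotation import revcomp
from exofrag.simulate import SimConfig, simulate_library
from exofrag.toyref import build_toy_reference


class TestToyReference:
    def test_structure(self, ann):
        cytosolic = ann.by_class("tRNA")
        assert len(cytosolic) >= 8
        assert len({g.family for g in cytosolic}) >= 4
        assert {g.strand for g in cytosolic} == {"+", "-"}
        assert any(len(g.blocks) == 2 for g in cytosolic)  # intron-containing
        assert len(ann.by_class("tRNA_mito")) == 1
        ygenes = {g.gene_id for g in ann.by_class("yRNA_gene")}
        assert ygenes == {"RNY1", "RNY3", "RNY4", "RNY5"}
        assert len(ann.by_class("yRNA_pseudogene")) >= 2
        assert len(ann.by_class("yRNA_repeat")) >= 2

    def test_rny5_is_84_nt(self, ann):
        assert ann["RNY5"].mature_length == 84

    def test_full_length_trna_with_cca_is_74_to_76_nt(self, ann):
        """Mature molecules including the nontemplated CCA span 74-76 nt."""
        for g in ann.by_class("tRNA"):
            assert 74 <= g.mature_length + 3 <= 76

    def test_some_genes_followed_by_templated_tail_context(self, ann, genome):
        from exofrag.annotation import downstream_context

        ctxs = {g.gene_id: downstream_context(g, genome, 3) for g in ann.by_class("tRNA")}
        assert any(c == "CCA" for c in ctxs.values())
        assert any(c.startswith("C") and c != "CCA" for c in ctxs.values())

    def test_files_are_deterministic(self, tmp_path):
        a = build_toy_reference(7, out_dir=str(tmp_path / "a"))
        b = build_toy_reference(7, out_dir=str(tmp_path / "b"))
        for key in a.paths:
            assert open(a.paths[key], "rb").read() == open(b.paths[key], "rb").read()


class TestSimulateLibrary:
    def test_determinism(self, toy):
        cfg = SimConfig(seed=3, n_reads=500)
        r1 = simulate_library(cfg, toy.annotation, toy.genome)
        r2 = simulate_library(cfg, toy.annotation, toy.genome)
        assert r1.truth.equals(r2.truth)
        assert r1.records == r2.records
        assert r1.raw_reads == r2.raw_reads

    def test_truth_conservation(self, wt_sim):
        truth = wt_sim.truth
        assert truth.read_id.is_unique
        cloned = set(truth[truth.cloned].read_id)
        assert {r.read_id for r in wt_sim.records} == cloned
        assert {rid for rid, _ in wt_sim.raw_reads} == cloned
        assert ((truth.drop_reason == "none") == truth.cloned).all()

    def test_every_alignment_matches_reference_strings(self, toy, wt_sim):
        """Self-consistency oracle: every M base equals the reference base and
        every tRNA read reconstructs as mature slice + tail."""
        ann, genome = toy.annotation, toy.genome
        truth = wt_sim.truth.set_index("read_id")
        for rec in wt_sim.records:
            contig = genome.contigs[rec.contig]
            for ri, gp in rec.aligned_pairs():
                base = contig[gp - 1]
                if rec.strand == "-":
                    base = revcomp(base)
                assert rec.seq[ri] == base, rec.read_id
            row = truth.loc[rec.read_id]
            if row.true_class in ("5half", "3half", "full_length"):
                gene = ann[row.gene_id]
                mature = gene.spliced_sequence(genome)
                tail = "" if row.true_tail in ("NONE", "NOT_TAILED") else row.true_tail
                if row.true_class == "5half":
                    assert rec.seq == mature[: len(rec.seq)]
                else:
                    core = len(rec.seq) - len(tail)
                    assert rec.seq == mature[len(mature) - core :] + tail

    def test_adapter_dropout_recorded(self, toy):
        cfg = SimConfig(seed=2, n_reads=2000, frac_no_adapter=0.1)
        sim = simulate_library(cfg, toy.annotation, toy.genome)
        flags = {r.read_id: r.has_adapter for r in sim.records}
        truth = sim.truth[sim.truth.cloned]
        assert (truth.read_id.map(flags) == truth.has_adapter).all()
        frac = 1 - truth.has_adapter.mean()
        assert 0.05 < frac < 0.15
        raw = dict(sim.raw_reads)
        for _, row in truth.iterrows():
            assert (cfg.adapter in raw[row.read_id]) == row.has_adapter

    def test_pnk_pairing(self, toy):
        on = simulate_library(SimConfig(seed=9, n_reads=4000, pnk_treated=True),
                              toy.annotation, toy.genome)
        off = simulate_library(SimConfig(seed=9, n_reads=4000, pnk_treated=False),
                               toy.annotation, toy.genome)
        cols = ["read_id", "family", "gene_id", "true_class", "true_tail", "length"]
        assert on.truth[cols].equals(off.truth[cols])
        cloned_on = set(on.truth[on.truth.cloned].read_id)
        cloned_off = set(off.truth[off.truth.cloned].read_id)
        assert cloned_off < cloned_on
        n3 = lambda t: ((t.true_class == "3half") & t.cloned).sum()
        assert n3(off.truth) < n3(on.truth)

    def test_methylation_block_mechanism(self, toy):
        base = dict(seed=6, n_reads=3000, p_methyl_block={"Gly-GCC": 1.0})
        blocked = simulate_library(SimConfig(**base), toy.annotation, toy.genome)
        healed = simulate_library(SimConfig(**base, demethylated=True),
                                  toy.annotation, toy.genome)
        t = blocked.truth
        gly_halves = t[(t.family == "Gly-GCC") & t.true_class.isin(["5half", "3half"])]
        assert len(gly_halves) > 0 and not gly_halves.cloned.any()
        assert (gly_halves.drop_reason == "methyl_block").all()
        assert healed.truth.cloned.all()

    def test_aminoacylation_blocks_intact_cca_molecules(self, toy):
        cfg = SimConfig(seed=6, n_reads=3000, p_aminoacyl=1.0, genotype="mutant")
        sim = simulate_library(cfg, toy.annotation, toy.genome)
        t = sim.truth
        cca = t[(t.true_tail == "CCA") & t.true_class.isin(["full_length", "3half"])]
        assert len(cca) > 0 and not cca.cloned.any()
        deac = simulate_library(
            SimConfig(seed=6, n_reads=3000, p_aminoacyl=1.0, genotype="mutant",
                      deacylated=True),
            toy.annotation, toy.genome)
        assert deac.truth.cloned.all()

    def test_infeasible_cleavage_window_fatal(self, toy):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_library(SimConfig(seed=1, n_reads=10, cleavage_window=(3, 38)),
                             toy.annotation, toy.genome)

    def test_overfull_fractions_fatal(self, toy):
        with pytest.raises(ValueError, match="exceed"):
            simulate_library(
                SimConfig(seed=1, n_reads=10, half_fraction=0.9, background_frac=0.2),
                toy.annotation, toy.genome)

    def test_written_outputs_deterministic(self, toy, tmp_path):
        cfg = SimConfig(seed=4, n_reads=300)
        p1 = simulate_library(cfg, toy.annotation, toy.genome).write(str(tmp_path / "x"))
        p2 = simulate_library(cfg, toy.annotation, toy.genome).write(str(tmp_path / "y"))
        for k in p1:
            assert open(p1[k], "rb").read() == open(p2[k], "rb").read()
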