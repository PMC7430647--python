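import random

import pytest

from _oracle import read_oracle
from exofrag.alignments import AlignmentRecord
from exofrag.pipeline import run_pipeline
from exofrag.qualify import Reason, Tail, detect_adapter, qualify_read, tail_call
from exofrag.simulate import SimConfig, simulate_library

ADAPTER = "TGGAATTCTC"


def mk(gene, genome, a, b, tail="", m_ext=0, read_id="r", **kw):
    """Read covering mature positions a..b plus a 3' tail (m_ext bases of it
    aligned past the annotation end, the rest soft-clipped).  Single-block
    genes only."""
    assert len(gene.blocks) == 1
    seq = gene.spliced_sequence(genome)[a - 1 : b] + tail
    cig = [("M", b - a + 1 + m_ext)]
    if len(tail) - m_ext:
        cig.append(("S", len(tail) - m_ext))
    if gene.strand == "+":
        start = gene.transcript_to_genomic(a)
    else:
        start = gene.transcript_to_genomic(b) - m_ext
    return AlignmentRecord(
        read_id=read_id, seq=seq, contig=gene.contig, strand=gene.strand,
        genomic_start=start, cigar=tuple(cig), **kw,
    )


@pytest.mark.parametrize(
    "raw, expected_trimmed, expected_flag",
    [
        ("ACGTACGT" + ADAPTER, "ACGTACGT", True),
        ("ACGTACGTACGTAA", "ACGTACGTACGTAA", False),
        ("ACGTACGT" + ADAPTER[:5], "ACGTACGT" + ADAPTER[:5], False),  # 5 < min_match
    ],
)
def test_detect_adapter(raw, expected_trimmed, expected_flag):
    assert detect_adapter(raw, ADAPTER, min_match=6) == (expected_trimmed, expected_flag)


class TestTailCall:
    def test_alignment_ending_at_mature_end_has_no_tail(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        assert tail_call(mk(g, genome, 34, g.mature_length), g, genome) is Tail.NONE

    def test_soft_clipped_cca_when_genome_context_differs(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]  # followed by GTT in the toy genome
        aln = mk(g, genome, 34, g.mature_length, tail="CCA")
        assert tail_call(aln, g, genome) is Tail.CCA

    def test_genome_templated_cca_aligned_past_end(self, ann, genome):
        g = ann["tRNA-Lys-CTT-1"]  # followed by CCA in the toy genome
        aln = mk(g, genome, 34, g.mature_length, tail="CCA", m_ext=3)
        assert tail_call(aln, g, genome) is Tail.CCA
        # the templated-tail exception: this is NOT a pre-tRNA read
        res = qualify_read(aln, g, genome)
        assert res.passed and res.tail is Tail.CCA

    def test_templated_cca_on_minus_strand_gene(self, ann, genome):
        g = ann["tRNA-Gly-GCC-2"]  # minus strand, downstream CCA
        aln = mk(g, genome, 34, g.mature_length, tail="CCA", m_ext=3)
        res = qualify_read(aln, g, genome)
        assert res.passed and res.tail is Tail.CCA

    def test_alignment_stopping_short_is_not_tailed(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 34, g.mature_length - 2)
        assert tail_call(aln, g, genome) is Tail.NOT_TAILED

    def test_non_cca_extra_sequence_is_other(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 34, g.mature_length, tail="G")
        assert tail_call(aln, g, genome) is Tail.OTHER


class TestQualifyCascade:
    def test_deletion_excluded(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        sp = g.spliced_sequence(genome)
        aln = AlignmentRecord(
            "r", sp[:20] + sp[21:34], g.contig, "+", g.genomic_start,
            (("M", 20), ("D", 1), ("M", 13)),
        )
        assert qualify_read(aln, g, genome).reason is Reason.INDEL_OR_INTRON

    def test_unannotated_intron_excluded(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        sp = g.spliced_sequence(genome)
        aln = AlignmentRecord(
            "r", sp[:10] + sp[15:25], g.contig, "+", g.genomic_start,
            (("M", 10), ("N", 5), ("M", 10)),
        )
        assert qualify_read(aln, g, genome).reason is Reason.INDEL_OR_INTRON

    def test_annotated_intron_skip_passes(self, ann, genome):
        g = ann["tRNA-Tyr-GTA-1"]  # intron between mature 37 and 38
        sp = g.spliced_sequence(genome)
        aln = AlignmentRecord(
            "r", sp[33:73], g.contig, "+", g.transcript_to_genomic(34),
            (("M", 4), ("N", 13), ("M", 36)),
        )
        res = qualify_read(aln, g, genome)
        assert res.passed and res.tail is Tail.NONE

    def test_missing_adapter_excluded(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 1, 33, has_adapter=False)
        assert qualify_read(aln, g, genome).reason is Reason.NO_ADAPTER

    def test_one_nucleotide_upstream_is_pre_trna(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        up = genome.fetch(g.contig, g.genomic_start - 1, g.genomic_start - 1)
        aln = AlignmentRecord(
            "r", up + g.spliced_sequence(genome)[:32], g.contig, "+",
            g.genomic_start - 1, (("M", 33),),
        )
        assert qualify_read(aln, g, genome).reason is Reason.PRE_TRNA

    def test_mitochondrial_gene_excluded(self, ann, genome):
        g = ann["tRNA-Mito-Phe-1"]
        aln = mk(g, genome, 1, 40)
        assert qualify_read(aln, g, genome).reason is Reason.MITO

    def test_secondary_alignment_excluded(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 1, 33, is_primary=False)
        assert qualify_read(aln, g, genome).reason is Reason.NOT_PRIMARY

    def test_five_prime_soft_clip_is_length_mismatch(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        sp = g.spliced_sequence(genome)
        aln = AlignmentRecord(
            "r", "G" + sp[:33], g.contig, "+", g.genomic_start,
            (("S", 1), ("M", 33)),
        )
        assert qualify_read(aln, g, genome).reason is Reason.LENGTH_MISMATCH

    def test_non_cca_soft_clip_is_length_mismatch(self, ann, genome):
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 34, g.mature_length, tail="G")
        assert qualify_read(aln, g, genome).reason is Reason.LENGTH_MISMATCH

    def test_tailed_read_longer_by_its_tail_passes(self, ann, genome):
        """Soft-clipped CCA may exceed the CIGAR match total by its own length."""
        g = ann["tRNA-Gly-GCC-1"]
        aln = mk(g, genome, 34, g.mature_length, tail="CCA")
        assert len(aln.seq) == aln.sum_matches + 3
        res = qualify_read(aln, g, genome)
        assert res.passed and res.tail is Tail.CCA
        # independent check by string matching
        reason, hits = read_oracle(aln.seq, g.spliced_sequence(genome))
        assert reason == "ok" and ("CCA", "3p") in hits


def test_reason_counts_invariant_to_read_order(toy, wt_sim):
    shuffled = wt_sim.records.copy()
    random.Random(0).shuffle(shuffled)
    out1 = run_pipeline(wt_sim.records, toy.annotation, toy.genome)
    out2 = run_pipeline(shuffled, toy.annotation, toy.genome)
    assert out1.reasons == out2.reasons


def test_reason_counts_conserve_primaries(toy, wt_sim):
    out = run_pipeline(wt_sim.records, toy.annotation, toy.genome)
    assert sum(out.reasons.values()) == out.n_mapped_primary == len(wt_sim.records)


def test_qualification_matches_string_oracle_with_adapter_dropout(toy):
    """Brute-force string matching reproduces reason and tail for every read."""
    cfg = SimConfig(seed=21, n_reads=800, frac_no_adapter=0.05)
    sim = simulate_library(cfg, toy.annotation, toy.genome)
    out = run_pipeline(sim.records, toy.annotation, toy.genome)
    qual = {q[0]: q for q in out.qualification}
    truth = sim.truth.set_index("read_id")
    checked = 0
    for rec in sim.records:
        row = truth.loc[rec.read_id]
        if row.true_class not in ("5half", "3half", "full_length"):
            continue
        gene = toy.annotation[row.gene_id]
        reason, hits = read_oracle(
            rec.seq,
            gene.spliced_sequence(toy.genome),
            is_mito=gene.gene_class == "tRNA_mito",
            has_adapter=rec.has_adapter,
        )
        _, _, got_reason, got_tail = qual[rec.read_id]
        assert got_reason == reason
        if reason == "ok":
            assert got_tail in {t for t, _ in hits}
            checked += 1
    assert checked > 400
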