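"""Deterministic toy reference genome + annotation for simulation and tests.

The toy emulates, at desk scale, the structure of a merged small-RNA
annotation: multiple cytosolic tRNA families on both strands (including two
identical-sequence Gly-GCC copies and one intron-containing Tyr-GTA gene), a
mitochondrial tRNA decoy, the four Y RNA genes (RNY5 at its native 84 nt),
RNY5 pseudogenes, and RepeatMasker-style HY repeat intervals carrying Y RNA
sequence.  Several tRNA genes are deliberately followed in the genome by
"CCA", "C.." or "CC." so the genome-templated tail exception is exercised.

Genome-encoded mature tRNA lengths are 71-73 nt; with the nontemplated CCA
tail the simulated full-length molecules are 74-76 nt.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationSet, GeneModel, GenomeRef, revcomp

__all__ = ["ToyReference", "build_toy_reference"]

_FILL = 60
_ALPHABET = np.array(list("ACGT"))

# (gene_id, family, strand, mature length, forced downstream context)
_TRNA_LAYOUT_A = [
    ("tRNA-Gly-GCC-1", "Gly-GCC", "+", 71, "GTT"),
    ("tRNA-Glu-CTC-1", "Glu-CTC", "+", 72, "CTG"),
    ("tRNA-Asp-GTC-1", "Asp-GTC", "-", 72, "CCG"),
    ("tRNA-Lys-CTT-1", "Lys-CTT", "+", 72, "CCA"),
    ("tRNA-Gly-CCC-1", "Gly-CCC", "-", 71, ""),
]
_TRNA_LAYOUT_B = [
    ("tRNA-Gly-GCC-2", "Gly-GCC", "-", 71, "CCA"),
    ("tRNA-Glu-TTC-1", "Glu-TTC", "+", 73, ""),
    ("tRNA-Val-TAC-1", "Val-TAC", "-", 73, ""),
    ("tRNA-Val-CAC-1", "Val-CAC", "+", 71, "CAG"),
]

_AA_ANTICODON = {
    "Gly-GCC": ("Gly", "GCC"),
    "Glu-CTC": ("Glu", "CTC"),
    "Asp-GTC": ("Asp", "GTC"),
    "Lys-CTT": ("Lys", "CTT"),
    "Gly-CCC": ("Gly", "CCC"),
    "Glu-TTC": ("Glu", "TTC"),
    "Val-TAC": ("Val", "TAC"),
    "Val-CAC": ("Val", "CAC"),
    "Tyr-GTA": ("Tyr", "GTA"),
    "Phe-GAA": ("Phe", "GAA"),
}

_Y_LENGTHS = {"RNY1": 112, "RNY3": 101, "RNY4": 95, "RNY5": 84}


@dataclass
class ToyReference:
    genome: GenomeRef
    annotation: AnnotationSet
    paths: dict[str, str] | None = None


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, n)])


class _Contig:
    def __init__(self, name: str, rng: np.random.Generator):
        self.name = name
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0

    def append(self, seq: str) -> tuple[int, int]:
        start = self.length + 1
        self.parts.append(seq)
        self.length += len(seq)
        return start, self.length

    def filler(self, n: int = _FILL) -> None:
        self.append(_rand_seq(self.rng, n))

    def sequence(self) -> str:
        return "".join(self.parts)


def _place_trna(contig: _Contig, gid, family, strand, length, ctx, rng, genes, mature_seqs):
    mature = mature_seqs.get(gid) or _rand_seq(rng, length)
    mature_seqs[gid] = mature
    if strand == "+":
        s, e = contig.append(mature)
        if ctx:
            contig.append(ctx)
    else:
        if ctx:
            contig.append(revcomp(ctx))
        s, e = contig.append(revcomp(mature))
    genes[gid] = GeneModel(gid, contig.name, strand, ((s, e),), "tRNA", family)
    contig.filler()


def _place_block_gene(contig: _Contig, gid, family, strand, seq, gene_class, genes):
    placed = seq if strand == "+" else revcomp(seq)
    s, e = contig.append(placed)
    genes[gid] = GeneModel(gid, contig.name, strand, ((s, e),), gene_class, family)
    contig.filler()


def build_toy_reference(seed: int, out_dir: str | None = None) -> ToyReference:
    """Build the toy genome and annotation; optionally write FASTA/GTF/TSV/BED.

    Deterministic: the same seed always yields byte-identical sequences and
    files.
    """
    rng = np.random.default_rng([int(seed), 101])
    genes: dict[str, GeneModel] = {}
    mature_seqs: dict[str, str] = {}

    # identical spliced sequence for the two Gly-GCC copies
    mature_seqs["tRNA-Gly-GCC-1"] = _rand_seq(rng, 71)
    mature_seqs["tRNA-Gly-GCC-2"] = mature_seqs["tRNA-Gly-GCC-1"]

    y_seq = {fam: _rand_seq(rng, L) for fam, L in _Y_LENGTHS.items()}
    tyr_mature = _rand_seq(rng, 73)
    tyr_intron = _rand_seq(rng, 13)
    mito_seq = _rand_seq(rng, 68)

    chrA = _Contig("chrA", rng)
    chrA.filler(80)
    for gid, fam, strand, L, ctx in _TRNA_LAYOUT_A:
        _place_trna(chrA, gid, fam, strand, L, ctx, rng, genes, mature_seqs)
    _place_block_gene(chrA, "RNY5", "RNY5", "+", y_seq["RNY5"], "yRNA_gene", genes)
    p3 = list(y_seq["RNY5"])
    p3[10], p3[55] = "A" if p3[10] != "A" else "G", "T" if p3[55] != "T" else "G"
    _place_block_gene(chrA, "RNY5P3", "RNY5", "-", "".join(p3), "yRNA_pseudogene", genes)
    _place_block_gene(chrA, "HY5_rep_a", "RNY5", "+", y_seq["RNY5"][:40], "yRNA_repeat", genes)
    _place_block_gene(
        chrA, "HY3_rep_a", "RNY3", "-", y_seq["RNY3"][:40], "yRNA_repeat", genes
    )
    _place_block_gene(chrA, "RNY3", "RNY3", "-", y_seq["RNY3"], "yRNA_gene", genes)
    chrA.filler(80)

    chrB = _Contig("chrB", rng)
    chrB.filler(80)
    for gid, fam, strand, L, ctx in _TRNA_LAYOUT_B:
        _place_trna(chrB, gid, fam, strand, L, ctx, rng, genes, mature_seqs)
    # intron-containing Tyr-GTA: 13-nt intron between mature positions 37 and 38
    exon1, exon2 = tyr_mature[:37], tyr_mature[37:]
    s1, e1 = chrB.append(exon1)
    chrB.append(tyr_intron)
    s2, e2 = chrB.append(exon2)
    genes["tRNA-Tyr-GTA-1"] = GeneModel(
        "tRNA-Tyr-GTA-1", "chrB", "+", ((s1, e1), (s2, e2)), "tRNA", "Tyr-GTA"
    )
    mature_seqs["tRNA-Tyr-GTA-1"] = tyr_mature
    chrB.filler()
    _place_block_gene(chrB, "RNY1", "RNY1", "+", y_seq["RNY1"], "yRNA_gene", genes)
    _place_block_gene(chrB, "RNY4", "RNY4", "-", y_seq["RNY4"], "yRNA_gene", genes)
    p1 = list(y_seq["RNY5"])
    p1[5], p1[70] = "C" if p1[5] != "C" else "T", "A" if p1[70] != "A" else "C"
    _place_block_gene(chrB, "RNY5P1", "RNY5", "+", "".join(p1), "yRNA_pseudogene", genes)
    _place_block_gene(chrB, "HY4_rep_b", "RNY4", "-", y_seq["RNY4"][:40], "yRNA_repeat", genes)
    _place_block_gene(chrB, "HY1_rep_b", "RNY1", "+", y_seq["RNY1"][:40], "yRNA_repeat", genes)
    chrB.filler(80)

    chrM = _Contig("chrM", rng)
    chrM.filler(50)
    s, e = chrM.append(mito_seq)
    genes["tRNA-Mito-Phe-1"] = GeneModel(
        "tRNA-Mito-Phe-1", "chrM", "+", ((s, e),), "tRNA_mito", "Phe-GAA"
    )
    chrM.filler(50)

    genome = GenomeRef(
        {"chrA": chrA.sequence(), "chrB": chrB.sequence(), "chrM": chrM.sequence()}
    )
    ann = AnnotationSet(genes=genes)
    ann.compute_indices(genome)

    paths = None
    if out_dir is not None:
        paths = _write_files(genome, ann, out_dir)
    return ToyReference(genome=genome, annotation=ann, paths=paths)


def _write_files(genome: GenomeRef, ann: AnnotationSet, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "toy_genome.fa"),
        "gtf": os.path.join(out_dir, "toy_genes.gtf"),
        "tsv": os.path.join(out_dir, "toy_trna_metadata.tsv"),
        "bed": os.path.join(out_dir, "toy_repeats.bed"),
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["gtf"], "w") as fh:
        for g in ann:
            if g.gene_class == "yRNA_repeat":
                continue
            gc = "tRNA" if g.gene_class == "tRNA_mito" else g.gene_class
            for s, e in sorted(g.blocks):
                attrs = f'gene_id "{g.gene_id}"; gene_class "{gc}"; family "{g.family}";'
                fh.write(
                    f"{g.contig}\ttoy\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    with open(paths["tsv"], "w") as fh:
        fh.write("gene_id\tamino_acid\tanticodon\tis_mito\n")
        for g in ann.by_class("tRNA", "tRNA_mito"):
            aa, ac = _AA_ANTICODON[g.family]
            fh.write(f"{g.gene_id}\t{aa}\t{ac}\t{int(g.gene_class == 'tRNA_mito')}\n")
    rny_to_hy = {"RNY1": "HY1", "RNY3": "HY3", "RNY4": "HY4", "RNY5": "HY5"}
    with open(paths["bed"], "w") as fh:
        for g in sorted(ann.by_class("yRNA_repeat"), key=lambda g: g.gene_id):
            s, e = g.blocks[0]
            fh.write(f"{g.contig}\t{s - 1}\t{e}\t{rny_to_hy[g.family]}\t0\t{g.strand}\n")
    return paths
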