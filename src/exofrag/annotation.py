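"""Reference genome and gene-model handling for small-RNA fragment analysis.

The annotation layer models two gene classes whose extracellular fragments the
pipeline quantifies: tRNA genes (cytosolic and mitochondrial, possibly
intron-containing) and Y RNA genes together with their pseudogenes and
RepeatMasker-derived repeat copies (families HY1/HY3/HY4/HY5, mapping to
RNY1/RNY3/RNY4/RNY5).

Internally every classification rule operates in 1-based inclusive
*mature-transcript* coordinates: position 1 is the 5' end of the spliced mature
RNA regardless of genomic strand, and intronic positions do not exist in the
coordinate system.  The nontemplated CCA tail of mature tRNAs is *not* part of
the annotated mature length; it appears only as extra read sequence past the
annotation end.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "GenomeRef",
    "GeneModel",
    "AnnotationSet",
    "NoOverlapError",
    "AnnotationError",
    "load_annotations",
    "transcript_coords",
    "downstream_context",
    "revcomp",
    "HY_TO_RNY",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: RepeatMasker HY family -> Y RNA gene family
HY_TO_RNY = {"HY1": "RNY1", "HY3": "RNY3", "HY4": "RNY4", "HY5": "RNY5"}

GENE_CLASSES = {"tRNA", "tRNA_mito", "yRNA_gene", "yRNA_pseudogene", "yRNA_repeat"}


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


class NoOverlapError(ValueError):
    """Alignment lies entirely outside the gene's exonic blocks."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRef:
    """In-memory reference genome: contig name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"contig {name!r} is empty")
            if set(seq) - set("ACGTN"):
                raise AnnotationError(f"contig {name!r} has non-ACGTN characters")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice on the forward strand."""
        return self.contigs[contig][start - 1 : end]

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeRef":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})


@dataclass(frozen=True)
class GeneModel:
    """A tRNA or Y RNA feature.

    ``blocks`` are the exons of the mature transcript as 1-based inclusive
    genomic intervals, ordered 5'->3' in transcript orientation (descending
    genomic coordinates for minus-strand genes).  Gaps between consecutive
    blocks are introns.
    """

    gene_id: str
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    gene_class: str
    family: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: malformed strand {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(f"{self.gene_id}: unknown class {self.gene_class!r}")
        if not self.blocks:
            raise AnnotationError(f"{self.gene_id}: no blocks")
        prev = None
        for s, e in self.blocks:
            if s > e:
                raise AnnotationError(f"{self.gene_id}: inverted block {(s, e)}")
            if prev is not None:
                ordered = s > prev[1] if self.strand == "+" else e < prev[0]
                if not ordered:
                    raise AnnotationError(
                        f"{self.gene_id}: blocks overlap or are out of transcript order"
                    )
            prev = (s, e)

    @property
    def mature_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)

    @property
    def genomic_start(self) -> int:
        return min(s for s, _ in self.blocks)

    @property
    def genomic_end(self) -> int:
        return max(e for _, e in self.blocks)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (1-based inclusive), sorted by coordinate."""
        sorted_blocks = sorted(self.blocks)
        out = []
        for (s1, e1), (s2, e2) in zip(sorted_blocks, sorted_blocks[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to the 1-based mature-transcript position.

        Returns None for intronic positions and positions outside the gene.
        """
        cum = 0
        for s, e in self.blocks:
            if s <= pos <= e:
                off = pos - s if self.strand == "+" else e - pos
                return cum + off + 1
            cum += e - s + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if tpos < 1 or tpos > self.mature_length:
            raise ValueError(f"transcript position {tpos} outside 1..{self.mature_length}")
        cum = 0
        for s, e in self.blocks:
            blen = e - s + 1
            if tpos <= cum + blen:
                off = tpos - cum - 1
                return s + off if self.strand == "+" else e - off
            cum += blen
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: GenomeRef) -> str:
        """Mature (intron-excised) sequence, 5'->3' of the transcript."""
        parts = []
        for s, e in self.blocks:
            chunk = genome.fetch(self.contig, s, e)
            parts.append(chunk if self.strand == "+" else revcomp(chunk))
        return "".join(parts)


@dataclass
class AnnotationSet:
    """All loaded gene models plus derived indices.

    identity_groups partitions cytosolic tRNA gene ids by exact spliced-sequence
    identity: reads mapping to any member of a group are counted together, since
    the copies are indistinguishable to an aligner.
    """

    genes: dict[str, GeneModel]
    identity_groups: dict[str, str] = field(default_factory=dict)
    family_index: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_class(self, *classes: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.gene_class in classes]

    def group_of(self, gene_id: str) -> str:
        return self.identity_groups.get(gene_id, gene_id)

    def compute_indices(self, genome: GenomeRef) -> None:
        """(Re)build identity groups and the family index."""
        by_seq: dict[str, list[str]] = {}
        for g in self.genes.values():
            if g.gene_class == "tRNA":
                by_seq.setdefault(g.spliced_sequence(genome), []).append(g.gene_id)
        self.identity_groups = {}
        for members in by_seq.values():
            label = min(members)
            for gid in sorted(members):
                self.identity_groups[gid] = label
        self.family_index = {}
        for g in self.genes.values():
            self.family_index.setdefault(g.family, []).append(g.gene_id)
        for ids in self.family_index.values():
            ids.sort()


def _open_text(path: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_gtf(gtf_path: str) -> dict[str, dict]:
    """Collect exon blocks + attributes per gene_id from a GTF file."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype != "exon":
            continue
        gid = feat.attributes["gene_id"][0]
        rec = genes.setdefault(
            gid,
            {
                "contig": feat.seqid,
                "strand": feat.strand,
                "blocks": [],
                "gene_class": feat.attributes.get("gene_class", ["tRNA"])[0],
                "family": feat.attributes.get("family", [""])[0],
            },
        )
        rec["blocks"].append((feat.start, feat.end))
    return genes


def load_annotations(
    genome: GenomeRef | str,
    gtf_path: str,
    metadata_tsv: str | None = None,
    repeats_bed: str | None = None,
) -> AnnotationSet:
    """Load gene models from GTF (+ tRNA metadata TSV, + repeat BED).

    The TSV refines tRNA records with amino acid / anticodon / mitochondrial
    status; the 6-column BED contributes Y RNA repeat intervals whose name
    column is the RepeatMasker HY family.  Returns an AnnotationSet with
    identity groups computed from the spliced sequences.
    """
    if isinstance(genome, str):
        genome = GenomeRef.from_fasta(genome)

    meta: dict[str, dict] = {}
    if metadata_tsv is not None:
        tbl = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
        for row in tbl.itertuples(index=False):
            meta[row.gene_id] = {
                "amino_acid": row.amino_acid,
                "anticodon": row.anticodon,
                "is_mito": str(row.is_mito).lower() in ("1", "true", "yes"),
            }

    genes: dict[str, GeneModel] = {}
    for gid, rec in _parse_gtf(gtf_path).items():
        gene_class = rec["gene_class"]
        family = rec["family"]
        if gid in meta:
            m = meta[gid]
            gene_class = "tRNA_mito" if m["is_mito"] else gene_class
            family = f"{m['amino_acid']}-{m['anticodon']}"
        if rec["contig"] not in genome.contigs:
            raise AnnotationError(f"{gid}: unknown contig {rec['contig']!r}")
        blocks = sorted(rec["blocks"])
        if rec["strand"] == "-":
            blocks = blocks[::-1]
        clen = len(genome.contigs[rec["contig"]])
        for s, e in blocks:
            if s < 1 or e > clen:
                raise AnnotationError(f"{gid}: block {(s, e)} outside contig bounds")
        genes[gid] = GeneModel(
            gene_id=gid,
            contig=rec["contig"],
            strand=rec["strand"],
            blocks=tuple(blocks),
            gene_class=gene_class,
            family=family,
        )

    if repeats_bed is not None:
        with _open_text(repeats_bed) as fh:
            for i, line in enumerate(fh):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                contig, start0, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) > 5 else "+"
                if name not in HY_TO_RNY:
                    raise AnnotationError(
                        f"repeat line {i + 1}: family {name!r} not in {sorted(HY_TO_RNY)}"
                    )
                gid = f"{name}_rep{i + 1}"
                genes[gid] = GeneModel(
                    gene_id=gid,
                    contig=contig,
                    strand=strand,
                    blocks=((start0 + 1, end),),
                    gene_class="yRNA_repeat",
                    family=HY_TO_RNY[name],
                )

    ann = AnnotationSet(genes=genes)
    ann.compute_indices(genome)
    return ann


def transcript_coords(ref_positions, gene: GeneModel) -> tuple[int, int]:
    """Transcript-coordinate span covered by an alignment's reference positions.

    ``ref_positions`` is any iterable of 1-based genomic positions consumed by
    alignment-match operations.  Positions falling in introns or outside the
    gene are ignored; if none fall inside, NoOverlapError is raised.
    """
    tpos = [t for p in ref_positions if (t := gene.genomic_to_transcript(p)) is not None]
    if not tpos:
        raise NoOverlapError(f"alignment does not overlap blocks of {gene.gene_id}")
    return min(tpos), max(tpos)


def downstream_context(gene: GeneModel, genome: GenomeRef, k: int) -> str:
    """The k nucleotides immediately 3' of the mature annotation end.

    Strand-aware: for minus-strand genes the genomic 5' flank is
    reverse-complemented.  A context running off the contig end is truncated
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    contig_seq = genome.contigs[gene.contig]
    if gene.strand == "+":
        end = gene.blocks[-1][1]
        avail = min(k, len(contig_seq) - end)
        ctx = genome.fetch(gene.contig, end + 1, end + avail)
    else:
        start = gene.blocks[-1][0]
        avail = min(k, start - 1)
        ctx = revcomp(genome.fetch(gene.contig, start - avail, start - 1))
    if avail < k:
        warnings.warn(
            f"{gene.gene_id}: downstream context truncated to {avail} nt at contig edge",
            stacklevel=2,
        )
    return ctx
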