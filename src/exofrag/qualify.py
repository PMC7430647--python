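"""Per-read qualification for the tRNA fragment analysis.

Reads enter the half/tail analysis only after an ordered exclusion cascade:
secondary alignments, mitochondrial tRNAs, alignments with indels or
unannotated introns, reads lacking the 3' adapter, reads whose trimmed length
disagrees with the sum of CIGAR matches, and precursor (pre-tRNA) reads are
all removed, each with a recorded reason.  The single exception to end-to-end
matching is a nontemplated 3' tail of exactly C, CC or CCA: its bases may be
soft-clipped, or — when the genome happens to continue in C/CC/CCA after the
gene — aligned past the annotation end without making the read a pre-tRNA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .alignments import AlignmentRecord
from .annotation import GeneModel, GenomeRef, NoOverlapError

__all__ = [
    "Tail",
    "TailCall",
    "Reason",
    "QualificationResult",
    "detect_adapter",
    "tail_call",
    "qualify_read",
]


class Tail(enum.Enum):
    NOT_TAILED = "not_tailed"  # alignment does not reach the mature 3' end
    NONE = "none"              # reaches the end with no extra 3' sequence
    C = "C"
    CC = "CC"
    CCA = "CCA"
    OTHER = "other"            # tailed, but extra 3' sequence is not C/CC/CCA


TailCall = Tail  # alias: a tail call is just the enum value

ALLOWED_TAILS = {Tail.C, Tail.CC, Tail.CCA}
_TAIL_BY_SEQ = {"": Tail.NONE, "C": Tail.C, "CC": Tail.CC, "CCA": Tail.CCA}


class Reason(enum.Enum):
    OK = "ok"
    MITO = "mito"
    INDEL_OR_INTRON = "indel_or_intron"
    NO_ADAPTER = "no_adapter"
    LENGTH_MISMATCH = "length_mismatch"
    PRE_TRNA = "pre_trna"
    NOT_PRIMARY = "not_primary"
    NO_GENE = "no_gene"


@dataclass(frozen=True)
class QualificationResult:
    passed: bool
    reason: Reason
    tail: Tail | None = None

    def __post_init__(self) -> None:
        assert self.passed == (self.reason is Reason.OK)


def detect_adapter(raw_seq: str, adapter: str, min_match: int = 6) -> tuple[str, bool]:
    """Locate the 3' adapter by exact prefix match and trim at it.

    ``has_adapter`` is True iff a prefix of ``adapter`` of at least
    ``min_match`` nt occurs in ``raw_seq``; the trimmed sequence is everything
    before the leftmost such occurrence.  This is deterministic plumbing that
    mirrors aligner-side adapter clipping, without its mismatch tolerance.
    """
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < min_match:
        raise ValueError("adapter shorter than min_match")
    idx = raw_seq.find(adapter[:min_match])
    if idx == -1:
        return raw_seq, False
    return raw_seq[:idx], True


def _transcript_pairs(aln: AlignmentRecord, gene: GeneModel):
    """Split M-aligned (read_idx, ref_pos) pairs into inside/outside the mature blocks."""
    inside, outside = [], []
    for ri, gp in aln.aligned_pairs():
        t = gene.genomic_to_transcript(gp)
        if t is None:
            outside.append((ri, gp))
        else:
            inside.append((ri, t))
    return inside, outside


def tail_call(aln: AlignmentRecord, gene: GeneModel, genome: GenomeRef) -> Tail:
    """Call the nontemplated 3'-tail status of a read on a tRNA gene.

    NOT_TAILED unless the aligned (M) bases reach the mature 3' end.  For
    tailed reads the tail is every read base past the position aligned to the
    annotation end — soft-clipped bases as well as genome-matching bases
    beyond the annotation (the templated-tail case).
    """
    inside, _ = _transcript_pairs(aln, gene)
    if not inside:
        raise NoOverlapError(f"{aln.read_id} does not overlap {gene.gene_id}")
    L = gene.mature_length
    t_by_pos = dict((t, ri) for ri, t in inside)
    if L not in t_by_pos:
        return Tail.NOT_TAILED
    tail_seq = aln.seq[t_by_pos[L] + 1 :]
    return _TAIL_BY_SEQ.get(tail_seq, Tail.OTHER)


def _intron_skips_annotated(aln: AlignmentRecord, gene: GeneModel) -> bool:
    """Every N op must coincide exactly with an annotated intron of the gene."""
    introns = set(gene.introns)
    return all(iv in introns for iv in aln.skip_intervals())


def _templated_tail_positions(gene: GeneModel, k: int) -> set[int]:
    """Genomic positions of the first k nt immediately 3' of the mature end."""
    if gene.strand == "+":
        end = gene.blocks[-1][1]
        return set(range(end + 1, end + k + 1))
    start = gene.blocks[-1][0]
    return set(range(start - k, start))


def qualify_read(
    aln: AlignmentRecord, gene: GeneModel | None, genome: GenomeRef
) -> QualificationResult:
    """Run the exclusion cascade for one read; first failure wins."""
    if not aln.is_primary:
        return QualificationResult(False, Reason.NOT_PRIMARY)
    if gene is None:
        return QualificationResult(False, Reason.NO_GENE)
    if gene.gene_class == "tRNA_mito":
        return QualificationResult(False, Reason.MITO)
    ops = {op for op, _ in aln.cigar}
    if "I" in ops or "D" in ops or not _intron_skips_annotated(aln, gene):
        return QualificationResult(False, Reason.INDEL_OR_INTRON)
    if not aln.has_adapter:
        return QualificationResult(False, Reason.NO_ADAPTER)

    inside, outside = _transcript_pairs(aln, gene)
    if not inside:
        return QualificationResult(False, Reason.PRE_TRNA)
    tail = tail_call(aln, gene, genome)

    # trimmed length must equal the sum of alignment matches; a C/CC/CCA tail
    # may exceed it by exactly its non-genome-matching (soft-clipped) part
    clip5, clip3 = aln.soft_clips()
    if len(aln.seq) != aln.sum_matches:
        tail_len = len(tail.value) if tail in ALLOWED_TAILS else 0
        if not (tail in ALLOWED_TAILS and clip5 == 0 and clip3 <= tail_len):
            return QualificationResult(False, Reason.LENGTH_MISMATCH)

    # pre-tRNA: any aligned base in an intron or outside the mature
    # annotation, unless it is part of a genome-templated C/CC/CCA tail
    if outside:
        if tail not in ALLOWED_TAILS:
            return QualificationResult(False, Reason.PRE_TRNA)
        allowed = _templated_tail_positions(gene, len(tail.value))
        if any(gp not in allowed for _, gp in outside):
            return QualificationResult(False, Reason.PRE_TRNA)

    return QualificationResult(True, Reason.OK, tail)
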