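"""Alignment records in RNA orientation, and SAM conversion.

An AlignmentRecord stores the read sequence 5'->3' of the original RNA and the
CIGAR in the same orientation (op order along the read).  For minus-strand SAM
records this means both are reversed relative to the file representation,
which makes 3'-end logic (nontemplated CCA tails, 3' soft clips) uniform
across strands.  ``genomic_start`` remains the SAM convention: 1-based
leftmost reference coordinate of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .annotation import GenomeRef, revcomp

__all__ = [
    "AlignmentRecord",
    "read_sam",
    "write_sam",
    "ADAPTER_TAG",
]

READ_CONSUMING = {"M", "I", "S"}
REF_CONSUMING = {"M", "D", "N"}

#: custom SAM tag carrying the 3'-adapter-found flag (1/0)
ADAPTER_TAG = "ZA"


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's placement, in RNA (5'->3') orientation."""

    read_id: str
    seq: str
    contig: str
    strand: str
    genomic_start: int
    cigar: tuple[tuple[str, int], ...]
    is_primary: bool = True
    has_adapter: bool = True
    nh: int = 1

    def __post_init__(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in READ_CONSUMING)
        if read_len != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR consumes {read_len} read bases, seq is {len(self.seq)}"
            )
        for op, n in self.cigar:
            if op not in "MIDNS":
                raise ValueError(f"{self.read_id}: unsupported CIGAR op {op!r}")
            if n < 1:
                raise ValueError(f"{self.read_id}: non-positive CIGAR length")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + self.ref_span - 1

    @property
    def sum_matches(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """(read_index_0based, genomic_pos_1based) for every M base, in read order.

        The reference is walked ascending for plus-strand alignments and
        descending from the right edge for minus-strand ones, so pairs follow
        the RNA 5'->3' direction.
        """
        step = 1 if self.strand == "+" else -1
        ref = self.genomic_start if self.strand == "+" else self.genomic_end
        ri = 0
        pairs: list[tuple[int, int]] = []
        for op, n in self.cigar:
            if op == "M":
                for _ in range(n):
                    pairs.append((ri, ref))
                    ri += 1
                    ref += step
            elif op in "DN":
                ref += step * n
            elif op in "IS":
                ri += n
        return pairs

    def skip_intervals(self) -> list[tuple[int, int]]:
        """Genomic (start, end) 1-based inclusive interval of every N op."""
        step = 1 if self.strand == "+" else -1
        ref = self.genomic_start if self.strand == "+" else self.genomic_end
        out = []
        for op, n in self.cigar:
            if op == "N":
                lo, hi = sorted((ref, ref + step * (n - 1)))
                out.append((lo, hi))
                ref += step * n
            elif op in "MD":
                ref += step * n
        return out

    def soft_clips(self) -> tuple[int, int]:
        """(5' clip length, 3' clip length) in RNA orientation."""
        five = self.cigar[0][1] if self.cigar[0][0] == "S" else 0
        three = self.cigar[-1][1] if len(self.cigar) > 1 and self.cigar[-1][0] == "S" else 0
        if len(self.cigar) == 1 and self.cigar[0][0] == "S":
            three = 0
        return five, three


def _cigar_to_sam(cigar: tuple[tuple[str, int], ...], strand: str) -> list[tuple[int, int]]:
    order = cigar if strand == "+" else cigar[::-1]
    opcode = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
    return [(opcode[op], n) for op, n in order]


def _cigar_from_sam(cigartuples, strand: str) -> tuple[tuple[str, int], ...]:
    opchar = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}
    cig = tuple((opchar[op], n) for op, n in cigartuples)
    return cig if strand == "+" else cig[::-1]


def write_sam(records: list[AlignmentRecord], genome: GenomeRef, path: str) -> None:
    """Write records as a text SAM file (sequences stored on the + strand)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()],
    }
    tid = {name: i for i, name in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = (0 if rec.strand == "+" else 16) | (0 if rec.is_primary else 256)
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.genomic_start - 1
            a.mapping_quality = 255
            a.cigartuples = _cigar_to_sam(rec.cigar, rec.strand)
            a.query_sequence = rec.seq if rec.strand == "+" else revcomp(rec.seq)
            a.set_tag("NH", rec.nh)
            a.set_tag(ADAPTER_TAG, 1 if rec.has_adapter else 0)
            out.write(a)


def read_sam(path: str, keep_secondary: bool = False) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into RNA-oriented AlignmentRecords.

    Secondary alignments are dropped by default: all counting downstream uses
    one primary alignment per read, including multimappers.
    """
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if a.is_secondary and not keep_secondary:
                continue
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence
            if strand == "-":
                seq = revcomp(seq)
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    seq=seq,
                    contig=a.reference_name,
                    strand=strand,
                    genomic_start=a.reference_start + 1,
                    cigar=_cigar_from_sam(a.cigartuples, strand),
                    is_primary=not a.is_secondary,
                    has_adapter=bool(a.get_tag(ADAPTER_TAG)) if a.has_tag(ADAPTER_TAG) else True,
                    nh=a.get_tag("NH") if a.has_tag("NH") else 1,
                )
            )
    return records
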