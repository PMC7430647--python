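"""Classification of qualified tRNA reads into 5'/3' halves and tail tabulation.

A 5' half starts within the first ``max_start5`` nucleotides of the mature
tRNA and ends inside the anticodon-loop window [loop_lo, loop_hi]; a 3' half
starts inside that window and ends within the last ``end3_margin`` nucleotides.
All boundaries are inclusive and expressed in 1-based mature-transcript
coordinates; nontemplated tail bases never extend the alignment end used for
the window tests.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .alignments import AlignmentRecord
from .annotation import AnnotationSet, GeneModel, GenomeRef, transcript_coords
from .qualify import Tail, qualify_read

__all__ = [
    "Half",
    "HalfWindows",
    "FragmentCall",
    "NotQualifiedError",
    "classify_half",
    "classify_read",
    "tail_status_table",
]

TAIL_CATEGORIES = (Tail.NONE, Tail.C, Tail.CC, Tail.CCA)


class NotQualifiedError(ValueError):
    """classify_read was handed a read that fails qualification."""


class Half:
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"
    OTHER = "other"


@dataclass(frozen=True)
class HalfWindows:
    """Window constants for half classification (1-based, inclusive)."""

    max_start5: int = 5
    loop_lo: int = 29
    loop_hi: int = 41
    end3_margin: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.max_start5 < self.loop_lo <= self.loop_hi):
            raise ValueError("require 1 <= max_start5 < loop_lo <= loop_hi")
        if self.end3_margin < 1:
            raise ValueError("end3_margin must be >= 1")


@dataclass(frozen=True)
class FragmentCall:
    """Per-read verdict for a qualified tRNA read."""

    read_id: str
    gene_id: str
    identity_group: str
    family: str
    half: str
    tail: Tail
    trimmed_length: int
    tstart: int = 0
    tend: int = 0


def classify_half(tstart: int, tend: int, L: int, w: HalfWindows = HalfWindows()) -> str:
    """Classify a transcript-coordinate span as a 5' half, 3' half or other."""
    if L < w.loop_hi + w.end3_margin:
        raise ValueError(
            f"mature length {L} shorter than loop_hi + end3_margin; windows would overlap"
        )
    if not (1 <= tstart <= tend <= L):
        raise ValueError(f"invalid span ({tstart}, {tend}) for length {L}")
    if tstart <= w.max_start5 and w.loop_lo <= tend <= w.loop_hi:
        return Half.FIVE_PRIME
    if w.loop_lo <= tstart <= w.loop_hi and tend >= L - w.end3_margin + 1:
        return Half.THREE_PRIME
    return Half.OTHER


def classify_read(
    aln: AlignmentRecord,
    gene: GeneModel,
    genome: GenomeRef,
    ann: AnnotationSet,
    w: HalfWindows = HalfWindows(),
) -> FragmentCall:
    """Qualify one read and classify it; raises NotQualifiedError on rejection."""
    result = qualify_read(aln, gene, genome)
    if not result.passed:
        raise NotQualifiedError(f"{aln.read_id}: {result.reason.value}")
    # window tests use only bases aligned inside the mature annotation;
    # templated tail extensions beyond the annotation end are excluded
    inside = (gp for _, gp in aln.aligned_pairs())
    tstart, tend = transcript_coords(inside, gene)
    half = classify_half(tstart, tend, gene.mature_length, w)
    return FragmentCall(
        read_id=aln.read_id,
        gene_id=gene.gene_id,
        identity_group=ann.group_of(gene.gene_id),
        family=gene.family,
        half=half,
        tail=result.tail,
        trimmed_length=len(aln.seq),
        tstart=tstart,
        tend=tend,
    )


def tail_status_table(calls) -> dict:
    """Counts and fractions of 3'-end tail status among tailed reads.

    Only reads whose tail is exactly NONE, C, CC or CCA enter the denominator;
    NOT_TAILED and OTHER reads are excluded.  With an empty denominator the
    fractions are undefined (NaN), not zero.
    """
    counts = Counter(c.tail for c in calls if c.tail in TAIL_CATEGORIES)
    total = sum(counts.values())
    return {
        "counts": {t.name: counts.get(t, 0) for t in TAIL_CATEGORIES},
        "fractions": {
            t.name: (counts.get(t, 0) / total if total else math.nan)
            for t in TAIL_CATEGORIES
        },
        "n_tailed": total,
    }
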