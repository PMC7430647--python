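"""Y RNA read assignment with the gene > pseudogene > repeat fallback.

Reads are assigned strand-specifically: first against annotated Y RNA genes,
then Y RNA pseudogenes; RepeatMasker-derived HY repeat intervals are consulted
only for reads that overlap no annotated feature at all (of any class).
Counts are aggregated per family — all pseudogenes and repeats of RNY5 count
as RNY5 — mirroring how multicopy Y RNA loci are indistinguishable in short
reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .alignments import AlignmentRecord
from .annotation import AnnotationSet, GeneModel

__all__ = ["YAssignment", "FeatureIndex", "assign_yrna", "yrna_summary"]

Y_FAMILIES = ("RNY1", "RNY3", "RNY4", "RNY5")


@dataclass(frozen=True)
class YAssignment:
    read_id: str
    family: str  # RNY1/RNY3/RNY4/RNY5 or "none"
    source_class: str  # gene/pseudogene/repeat or "none"
    trimmed_length: int

    def __post_init__(self) -> None:
        assert (self.family == "none") == (self.source_class == "none")


class FeatureIndex:
    """Strand-specific interval lookup over an AnnotationSet.

    Built once per annotation; shared by the tRNA gene-resolution step and
    the Y RNA assignment step.
    """

    def __init__(self, ann: AnnotationSet):
        from intervaltree import IntervalTree

        self.ann = ann
        self._annotated: dict[tuple[str, str], "IntervalTree"] = defaultdict(IntervalTree)
        self._repeats: dict[tuple[str, str], "IntervalTree"] = defaultdict(IntervalTree)
        for g in ann:
            tree = self._repeats if g.gene_class == "yRNA_repeat" else self._annotated
            for s, e in g.blocks:
                # intervaltree uses half-open intervals
                tree[(g.contig, g.strand)][s : e + 1] = g

    @staticmethod
    def _overlaps(tree, aln: AlignmentRecord) -> list[tuple[int, GeneModel]]:
        hits = tree[(aln.contig, aln.strand)].overlap(aln.genomic_start, aln.genomic_end + 1)
        by_gene: dict[str, int] = defaultdict(int)
        genes: dict[str, GeneModel] = {}
        for iv in hits:
            g = iv.data
            ov = min(iv.end - 1, aln.genomic_end) - max(iv.begin, aln.genomic_start) + 1
            by_gene[g.gene_id] += ov
            genes[g.gene_id] = g
        return [(by_gene[gid], genes[gid]) for gid in by_gene]

    def best_feature(self, aln: AlignmentRecord, classes=None) -> GeneModel | None:
        """Largest-overlap annotated feature (ties broken by gene_id)."""
        cands = self._overlaps(self._annotated, aln)
        if classes is not None:
            cands = [(ov, g) for ov, g in cands if g.gene_class in classes]
        if not cands:
            return None
        return min(cands, key=lambda t: (-t[0], t[1].gene_id))[1]

    def best_repeat(self, aln: AlignmentRecord) -> GeneModel | None:
        cands = self._overlaps(self._repeats, aln)
        if not cands:
            return None
        return min(cands, key=lambda t: (-t[0], t[1].gene_id))[1]


def assign_yrna(
    aln: AlignmentRecord, ann: AnnotationSet, index: FeatureIndex | None = None
) -> YAssignment:
    """Assign one primary alignment to a Y RNA family, or to none."""
    if index is None:
        index = FeatureIndex(ann)
    feat = index.best_feature(aln)
    if feat is not None:
        if feat.gene_class == "yRNA_gene":
            return YAssignment(aln.read_id, feat.family, "gene", len(aln.seq))
        if feat.gene_class == "yRNA_pseudogene":
            return YAssignment(aln.read_id, feat.family, "pseudogene", len(aln.seq))
        # assigned to some other annotated feature (e.g. a tRNA): not a Y read,
        # and repeats are not consulted
        return YAssignment(aln.read_id, "none", "none", len(aln.seq))
    rep = index.best_repeat(aln)
    if rep is not None:
        return YAssignment(aln.read_id, rep.family, "repeat", len(aln.seq))
    return YAssignment(aln.read_id, "none", "none", len(aln.seq))


def yrna_summary(assignments) -> dict:
    """Family shares, source-class shares and per-family 1-nt length histograms."""
    assigned = [a for a in assignments if a.family != "none"]
    n = len(assigned)
    fam_counts = Counter(a.family for a in assigned)
    cls_counts = Counter(a.source_class for a in assigned)
    hists: dict[str, dict[int, int]] = {}
    for a in assigned:
        hists.setdefault(a.family, Counter())[a.trimmed_length] += 1
    return {
        "n_assigned": n,
        "family_counts": dict(fam_counts),
        "family_shares": {f: c / n for f, c in fam_counts.items()} if n else {},
        "source_class_shares": {c: v / n for c, v in cls_counts.items()} if n else {},
        "length_hist": {f: dict(sorted(h.items())) for f, h in hists.items()},
    }
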