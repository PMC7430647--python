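# Methods

## Coordinate model

All classification rules operate in 1-based inclusive **mature-transcript
coordinates**: position 1 is the spliced transcript's 5' end regardless of
genomic strand, and intronic positions are excised from the coordinate
system. External files keep their native conventions (GTF 1-based, BED
0-based half-open); conversion happens once at load. The nontemplated CCA
tail of mature tRNAs is *not* part of the annotated mature length — windows
are relative to the genome-encoded annotation, and tail bases appear only as
read sequence past the annotation end. For the few intron-containing tRNAs,
half windows are evaluated on spliced coordinates, consistent with halves
deriving from mature (spliced) tRNAs; the pre-tRNA rule independently
excludes any read with aligned bases inside an intron.

Alignment records are normalized to RNA orientation (sequence and CIGAR
5'→3' of the original molecule); minus-strand SAM records are
reverse-complemented on read-in. This makes every 3'-end rule — tail
calling, the templated-tail exception, soft-clip handling — strand-uniform,
and strand symmetry is asserted by tests rather than re-derived per rule.

## Qualification cascade

Reasons are mutually exclusive and assigned in fixed order: `not_primary`,
`no_gene`, `mito`, `indel_or_intron`, `no_adapter`, `length_mismatch`,
`pre_trna`, `ok`. Choices made where the rules leave room:

* An N (skip) CIGAR operation is accepted only when its genomic interval
  equals an annotated intron exactly; any other N counts as an unannotated
  intron and disqualifies.
* The trimmed-length rule (`len(seq) == ΣM`) is relaxed only for 3' tails of
  exactly C/CC/CCA: the read may exceed ΣM by the soft-clipped part of that
  tail. 5' soft clips of any length disqualify — the exception is stated
  for 3' tails only.
* When the genome happens to continue in C, CC or CCA after a gene, tail
  bases align as M past the annotation end. Such reads are treated as
  tailed, never as pre-tRNA, even where a longer genomic match would be
  possible.
* Secondary alignments are dropped before the cascade; every count
  downstream uses one primary alignment per read (multimappers included),
  and the NH tag is carried for reporting only.
* Reads whose best-overlapping feature is not a tRNA (or that overlap
  nothing) are `no_gene`; feature resolution is strand-specific,
  largest-overlap, ties broken lexicographically by gene id.
* Adapter detection (for synthetic raw reads) is an exact ≥6-nt prefix
  match of the adapter — deterministic, unlike an aligner's
  mismatch-tolerant clipping; the threshold is configurable.

## Half classification and summaries

Window constants default to `max_start5=5`, `loop_lo=29`, `loop_hi=41`,
`end3_margin=5`, all boundaries inclusive; they are configuration, not
literals, so sensitivity analyses are possible. A mature length below
`loop_hi + end3_margin` is a configuration error (the windows would
overlap). The alignment end used for window tests is the last base aligned
*inside* the annotation; tail bases never extend it.

Dataset summaries use all mapped primary alignments as the denominator of
the half fraction (background and Y RNA reads included). Family tables
aggregate by isoacceptor (amino acid + anticodon) and half type; identity
groups (exact spliced-sequence equality) are the unit of the 5'/3'
imbalance statistic, whose threshold defaults to 10:1 with a floor of 10
halves per group (groups below the floor leave the denominator; the floor
is configurable and reported). Replicate summaries report mean ± sample SD;
a single replicate reports no SD rather than zero. Percentages are rounded
to one decimal in printed tables.

## Y RNA assignment

Strand-specific overlap (≥1 nt) against Y RNA genes, then pseudogenes;
RepeatMasker HY1/HY3/HY4/HY5 intervals are consulted only for reads
overlapping *no* annotated feature of any class. Counts aggregate per family
(HY1→RNY1 etc.), so relabeling pseudogene ids never changes family counts.
Y RNA reads do not pass the tRNA qualification cascade — only primariness
and strand are enforced — and no positional window rule is applied to Y
fragments; they are summarized by 1-nt length histograms (the dominant RNY5
5' species appears as the 33-nt mode).

## The simulator

`build_toy_reference` lays out a three-contig toy genome: nine cytosolic
tRNA genes from eight isoacceptor families on both strands (two
identical-sequence Gly-GCC copies; one Tyr-GTA with a 13-nt intron between
mature positions 37 and 38), one mitochondrial decoy, the four Y RNA genes
(RNY5 at its native 84 nt), two RNY5 pseudogenes and four HY repeat
intervals carrying Y RNA sequence. Genome-encoded mature tRNA lengths are
71–73 nt so full-length molecules with CCA are 74–76 nt. Several genes are
deliberately followed by CCA, C or CC in the genome to exercise the
templated-tail exception. Everything is deterministic per seed,
byte-for-byte, including the written FASTA/GTF/TSV/BED/SAM/FASTQ files.

`simulate_library` draws each molecule's class from
(background, Y RNA, mitochondrial, tRNA half, full-length tRNA) with
configurable fractions. Wild-type defaults are the observed composition of
PNK-treated processed libraries: half fraction 0.173, 5' share 0.53, tail
distribution C 0.70 / NONE 0.20 / CCA 0.05 / CC 0.05; the nuclease-null
genotype defaults to half fraction 0.016 with CCA 0.90 and mostly
full-length molecules. Cleavage positions are uniform over transcript
positions 31–38 (the anticodon loop); the observed dominant per-gene sites
are sharper in real data, so the window is configurable per study. Family
weights for halves are side-conditional (separate 5' and 3' tables patterned
on the observed abundance ranking, Asp-GTC 3' > Gly-GCC 5' > Glu-CTC 5'),
which keeps the global 5'/3' split an independent scalar parameter.

The library-preparation model acts per molecule, on a random-number stream
separate from molecule generation, so two runs differing only in treatment
flags share identical molecule sets (paired comparisons):

* **End chemistry.** Cleavage leaves a 2'-3' cyclic phosphate and a 5'
  hydroxyl. Each unhealed end independently fails cloning with probability
  `p_end_fail` (default 0.8) when PNK is off. A 5' half has one cleaved
  end; a 3' half has two when its CCA tail was also trimmed and one when
  the tail is intact; a tail-trimmed full-length molecule has one. The
  per-end model reproduces the qualitative observation that omitting PNK
  depletes 3' halves disproportionately; a drop-everything model could not.
* **Methylation.** Halves carry an RT-blocking methylation with probability
  `p_methyl_block` (scalar or per-family), dropping them unless the sample
  is demethylated.
* **Aminoacylation.** Molecules with an intact CCA 3' end are aminoacylated
  with probability `p_aminoacyl`, dropping them unless deacylated.
* **Adapter.** A fraction `frac_no_adapter` of cloned reads lacks the 3'
  adapter in the raw read; they are still emitted and mapped (the insert
  simply exceeds the read) but fail the adapter filter downstream.

The bias knobs default to neutral (PNK on, no methylation or aminoacylation,
full adapter presence) because the default composition targets are
themselves measured downstream of those biases in PNK-treated libraries;
the knobs exist to demonstrate mechanisms, not to recalibrate defaults.

What the simulator does **not** model: sequencing errors and mismatch
handling (assumed filtered by the mapper upstream), per-gene cleavage-site
structure, quality scores, EV versus non-EV compartments, and quantitative
enzyme dose response. Passing tests therefore certify the classification
logic and the stated biases, not robustness to alignment noise.

## Problem sizes and numerics

Recovery tests use libraries of 5 000–20 000 reads — large enough that
3-binomial-SD bands are a few tenths of a percentage point, small enough to
run the whole suite in well under a minute of simulation time. Exhaustive
window checks enumerate every (start, end) pair for mature lengths 46–100.
Empty denominators (no tailed reads, no halves, no eligible imbalance
groups) yield NaN, never zero. Infinite imbalance ratios (one half absent)
fail the 10:1 threshold by definition. Tie-breaks everywhere are
lexicographic by gene id after the primary criterion, making all outputs
order-independent.
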