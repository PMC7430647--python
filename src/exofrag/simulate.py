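"""Simulation of extracellular small-RNA fragment libraries with ground truth.

The generator draws library molecules according to the biogenesis model of
extracellular RNA processing by a secreted ribonuclease: full-length mature
tRNAs carry a nontemplated CCA tail; cleavage in the anticodon loop produces
5' and 3' halves; the CCA tail is usually trimmed to C (cut between the two
cytidines) in processed samples; Y RNAs yield a dominant 5' fragment (33 nt
for RNY5) and shorter 3' fragments.  Each molecule then passes a
library-preparation model: ribonuclease cleavage leaves 2'-3' cyclic
phosphate / 5'-OH ends that resist adapter ligation unless healed by PNK
(3' halves carry two such ends when their CCA tail is also trimmed, 5' halves
one, so 3' halves are more PNK-sensitive); base methylations block reverse
transcription unless the sample is demethylated; 3' aminoacylation blocks
ligation unless deacylated.

Alignment records are constructed by exact placement with correct CIGARs:
N skips across annotated introns, genome-templated tail bases as M
extensions past the annotation end, and the remaining nontemplated tail
soft-clipped.  Every molecule (cloned or dropped) appears once in the truth
table, which downstream recovery tests compare against pipeline output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord, write_sam
from .annotation import AnnotationSet, GeneModel, GenomeRef, downstream_context, revcomp
from .toyref import ToyReference, build_toy_reference

__all__ = ["SimConfig", "SimResult", "simulate_library", "build_toy_reference"]

_GENOTYPE_DEFAULTS = {
    "WT": {
        "half_fraction": 0.173,
        "split5": 0.53,
        "tail_probs": {"CCA": 0.05, "CC": 0.05, "C": 0.70, "NONE": 0.20},
        "y_class_weights": {"y5frag": 0.55, "y3frag": 0.25, "y_full": 0.20},
    },
    "mutant": {
        "half_fraction": 0.016,
        "split5": 0.53,
        "tail_probs": {"CCA": 0.90, "CC": 0.03, "C": 0.03, "NONE": 0.04},
        "y_class_weights": {"y5frag": 0.09, "y3frag": 0.06, "y_full": 0.85},
    },
}

# side-conditional isoacceptor weights for half molecules (relative)
_FAMILY_WEIGHTS_5 = {
    "Gly-GCC": 24.9,
    "Glu-CTC": 17.3,
    "Lys-CTT": 2.8,
    "Val-CAC": 2.4,
    "Gly-CCC": 1.6,
    "Val-TAC": 1.5,
}
_FAMILY_WEIGHTS_3 = {
    "Asp-GTC": 25.8,
    "Glu-TTC": 7.3,
    "Glu-CTC": 6.7,
    "Val-TAC": 5.5,
    "Tyr-GTA": 2.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one simulated library.

    Unset fraction/tail fields are filled from the genotype defaults: the WT
    genotype fragments most tRNAs into halves with a C-dominant tail, the
    mutant emits mostly full-length molecules with intact CCA.
    """

    seed: int = 0
    n_reads: int = 20_000
    genotype: str = "WT"
    half_fraction: float | None = None
    split5: float | None = None
    cleavage_window: tuple[int, int] = (31, 38)
    tail_probs: dict[str, float] | None = None
    family_weights_5: dict[str, float] = field(default_factory=lambda: dict(_FAMILY_WEIGHTS_5))
    family_weights_3: dict[str, float] = field(default_factory=lambda: dict(_FAMILY_WEIGHTS_3))
    family_abundances: dict[str, float] | None = None  # full-length molecules
    yrna_frac: float = 0.08
    y_family_weights: dict[str, float] = field(
        default_factory=lambda: {"RNY5": 0.56, "RNY4": 0.20, "RNY3": 0.14, "RNY1": 0.10}
    )
    y_source_weights: dict[str, float] = field(
        default_factory=lambda: {"gene": 0.60, "pseudogene": 0.25, "repeat": 0.15}
    )
    y_class_weights: dict[str, float] | None = None
    background_frac: float = 0.10
    mito_frac: float = 3e-5
    pnk_treated: bool = True
    demethylated: bool = False
    deacylated: bool = False
    p_methyl_block: float | dict = 0.0
    p_aminoacyl: float = 0.0
    p_end_fail: float = 0.8
    adapter: str = "TGGAATTCTC"
    frac_no_adapter: float = 0.0

    def resolved(self) -> "SimConfig":
        if self.genotype not in _GENOTYPE_DEFAULTS:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        g = _GENOTYPE_DEFAULTS[self.genotype]
        cfg = replace(
            self,
            half_fraction=self.half_fraction if self.half_fraction is not None else g["half_fraction"],
            split5=self.split5 if self.split5 is not None else g["split5"],
            tail_probs=self.tail_probs if self.tail_probs is not None else dict(g["tail_probs"]),
            y_class_weights=(
                self.y_class_weights
                if self.y_class_weights is not None
                else dict(g["y_class_weights"])
            ),
        )
        if abs(sum(cfg.tail_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tail_probs must sum to 1")
        rest = 1.0 - (cfg.half_fraction + cfg.yrna_frac + cfg.background_frac + cfg.mito_frac)
        if rest < 0:
            raise ValueError("class fractions exceed 1")
        return cfg


@dataclass
class SimResult:
    records: list[AlignmentRecord]
    truth: pd.DataFrame
    config: SimConfig
    genome: GenomeRef
    raw_reads: list[tuple[str, str]]  # (read_id, raw sequence incl. adapter ends)

    @property
    def n_mapped_primary(self) -> int:
        return len(self.records)

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "sam": os.path.join(out_dir, "reads.sam"),
            "fastq": os.path.join(out_dir, "reads.fastq"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        write_sam(self.records, self.genome, paths["sam"])
        with open(paths["fastq"], "w") as fh:
            for rid, raw in self.raw_reads:
                fh.write(f"@{rid}\n{raw}\n+\n{'I' * len(raw)}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _choice(rng: np.random.Generator, weights: dict):
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _methyl_prob(p_methyl_block, family: str, side: str) -> float:
    if isinstance(p_methyl_block, dict):
        v = p_methyl_block.get(family, 0.0)
        if isinstance(v, dict):
            return float(v.get(side, 0.0))
        if isinstance(v, (tuple, list)):
            return float(v[0] if side == "5" else v[1])
        return float(v)
    return float(p_methyl_block)


def _build_alignment(
    read_id: str,
    gene: GeneModel,
    genome: GenomeRef,
    tstart: int,
    tend: int,
    tail: str,
    has_adapter: bool,
    nh: int,
) -> AlignmentRecord:
    """Exact-placement alignment of mature positions tstart..tend plus a tail."""
    seq = gene.spliced_sequence(genome)[tstart - 1 : tend] + tail
    # M runs over the covered blocks (transcript orientation), N across the
    # annotated intron whenever the alignment covers blocks on both sides
    cigar: list[tuple[str, int]] = []
    cum = 0
    pending_gap = 0
    for i, (s, e) in enumerate(gene.blocks):
        blen = e - s + 1
        lo, hi = cum + 1, cum + blen  # transcript span of this block
        a, b = max(tstart, lo), min(tend, hi)
        if a <= b:
            if cigar and pending_gap:
                cigar.append(("N", pending_gap))
            cigar.append(("M", b - a + 1))
            pending_gap = 0
        if i + 1 < len(gene.blocks):
            nxt = gene.blocks[i + 1]
            gap = (nxt[0] - e - 1) if gene.strand == "+" else (s - nxt[1] - 1)
            pending_gap += gap
        cum += blen
    # genome-templated tail prefix extends the final M; the rest is soft-clipped
    m_ext = 0
    if tail and tend == gene.mature_length:
        ctx = downstream_context(gene, genome, len(tail))
        while m_ext < len(ctx) and tail[m_ext] == ctx[m_ext]:
            m_ext += 1
        if m_ext:
            cigar[-1] = ("M", cigar[-1][1] + m_ext)
        if len(tail) - m_ext:
            cigar.append(("S", len(tail) - m_ext))
    elif tail:
        cigar.append(("S", len(tail)))
    if gene.strand == "+":
        start = gene.transcript_to_genomic(tstart)
    else:
        start = gene.transcript_to_genomic(tend) - m_ext
    return AlignmentRecord(
        read_id=read_id,
        seq=seq,
        contig=gene.contig,
        strand=gene.strand,
        genomic_start=start,
        cigar=tuple(cigar),
        has_adapter=has_adapter,
        nh=nh,
    )


def _background_pool(genome: GenomeRef, ann: AnnotationSet, margin: int = 45):
    """Unannotated intervals (1-based inclusive) long enough to sample decoys."""
    pool = []
    for contig, seq in genome.contigs.items():
        occupied = sorted(
            (max(1, g.genomic_start - margin), min(len(seq), g.genomic_end + margin))
            for g in ann
            if g.contig == contig
        )
        cur = 1
        for s, e in occupied:
            if s - 1 >= cur + 49:
                pool.append((contig, cur, s - 1))
            cur = max(cur, e + 1)
        if len(seq) >= cur + 49:
            pool.append((contig, cur, len(seq)))
    return pool


def _validate_windows(cfg: SimConfig, trna_genes: list[GeneModel]) -> None:
    lo, hi = cfg.cleavage_window
    if lo > hi:
        raise ValueError("empty cleavage window")
    for g in trna_genes:
        if not (5 < lo and hi <= g.mature_length - 5):
            raise ValueError(
                f"cleavage window {cfg.cleavage_window} infeasible for "
                f"{g.gene_id} (mature length {g.mature_length})"
            )


def simulate_library(
    cfg: SimConfig, ann: AnnotationSet, genome: GenomeRef
) -> SimResult:
    """Simulate one library: alignment records, raw reads and a truth table."""
    cfg = cfg.resolved()
    rng_mol = np.random.default_rng([int(cfg.seed), 7])
    rng_clone = np.random.default_rng([int(cfg.seed), 13])

    trna_by_family: dict[str, list[GeneModel]] = {}
    for g in ann.by_class("tRNA"):
        trna_by_family.setdefault(g.family, []).append(g)
    for fams in trna_by_family.values():
        fams.sort(key=lambda g: g.gene_id)
    mito_genes = sorted(ann.by_class("tRNA_mito"), key=lambda g: g.gene_id)
    y_by_family: dict[str, dict[str, list[GeneModel]]] = {}
    for g in ann.by_class("yRNA_gene", "yRNA_pseudogene", "yRNA_repeat"):
        cls = {"yRNA_gene": "gene", "yRNA_pseudogene": "pseudogene", "yRNA_repeat": "repeat"}[
            g.gene_class
        ]
        y_by_family.setdefault(g.family, {}).setdefault(cls, []).append(g)
    for d in y_by_family.values():
        for lst in d.values():
            lst.sort(key=lambda g: g.gene_id)

    w5 = {f: w for f, w in cfg.family_weights_5.items() if f in trna_by_family}
    w3 = {f: w for f, w in cfg.family_weights_3.items() if f in trna_by_family}
    wfull = cfg.family_abundances or {f: 1.0 for f in trna_by_family}
    wfull = {f: w for f, w in wfull.items() if f in trna_by_family}
    if not (w5 and w3 and wfull):
        raise ValueError("no tRNA families available for the configured weights")
    _validate_windows(cfg, [g for fams in trna_by_family.values() for g in fams])

    wy = {f: w for f, w in cfg.y_family_weights.items() if f in y_by_family}
    if cfg.yrna_frac > 0 and not wy:
        raise ValueError("yrna_frac > 0 but annotation has no Y RNA features")
    pool = _background_pool(genome, ann)
    if cfg.background_frac > 0 and not pool:
        raise ValueError("no unannotated intervals available for background reads")

    p_bg, p_y = cfg.background_frac, cfg.yrna_frac
    p_half = cfg.half_fraction
    p_mito = cfg.mito_frac if mito_genes else 0.0

    records: list[AlignmentRecord] = []
    raw_reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_reads):
        rid = f"sim{i:06d}"
        u = rng_mol.random()
        side = "5" if rng_mol.random() < cfg.split5 else "3"
        cleave = int(rng_mol.integers(cfg.cleavage_window[0], cfg.cleavage_window[1] + 1))
        tail = _choice(rng_mol, cfg.tail_probs)
        tail_seq = "" if tail == "NONE" else tail
        rand_ends = _rand4(rng_mol), _rand4(rng_mol)

        rec: AlignmentRecord | None = None
        fam = gene_id = ""
        true_tail = ""
        if u < p_bg:
            cls = "background"
            contig, lo, hi = pool[int(rng_mol.integers(0, len(pool)))]
            ln = int(rng_mol.integers(20, 41))
            start = int(rng_mol.integers(lo, hi - ln + 2))
            strand = "+" if rng_mol.random() < 0.5 else "-"
            chunk = genome.fetch(contig, start, start + ln - 1)
            if strand == "-":
                chunk = revcomp(chunk)
            rec = AlignmentRecord(
                read_id=rid, seq=chunk, contig=contig, strand=strand,
                genomic_start=start, cigar=(("M", ln),),
            )
        elif u < p_bg + p_y:
            yfam = _choice(rng_mol, wy)
            ycls = _choice(rng_mol, cfg.y_class_weights)
            sources = y_by_family[yfam]
            src_w = {
                c: w
                for c, w in cfg.y_source_weights.items()
                if c in sources and (ycls == "y5frag" or c != "repeat")
            }
            src_cls = _choice(rng_mol, src_w)
            feats = sources[src_cls]
            feat = feats[int(rng_mol.integers(0, len(feats)))]
            L = feat.mature_length
            if ycls == "y5frag":
                ts, te = 1, min(33, L)
            elif ycls == "y3frag":
                ln = int(rng_mol.integers(24, 34))
                ts, te = L - min(ln, L - 1) + 1, L
            else:
                ts, te = 1, L
            cls, fam, gene_id = ycls, yfam, feat.gene_id
            rec = _build_alignment(rid, feat, genome, ts, te, "", True, 1)
        elif u < p_bg + p_y + p_mito:
            cls = "full_length"
            feat = mito_genes[int(rng_mol.integers(0, len(mito_genes)))]
            fam, gene_id = feat.family, feat.gene_id
            true_tail = tail
            rec = _build_alignment(rid, feat, genome, 1, feat.mature_length, tail_seq, True, 1)
        elif u < p_bg + p_y + p_mito + p_half:
            cls = "5half" if side == "5" else "3half"
            fam = _choice(rng_mol, w5 if side == "5" else w3)
            copies = trna_by_family[fam]
            gene = copies[int(rng_mol.integers(0, len(copies)))]
            gene_id = gene.gene_id
            nh = len(copies)
            if side == "5":
                true_tail = "NOT_TAILED"
                rec = _build_alignment(rid, gene, genome, 1, cleave, "", True, nh)
            else:
                true_tail = tail
                rec = _build_alignment(
                    rid, gene, genome, cleave + 1, gene.mature_length, tail_seq, True, nh
                )
        else:
            cls = "full_length"
            fam = _choice(rng_mol, wfull)
            copies = trna_by_family[fam]
            gene = copies[int(rng_mol.integers(0, len(copies)))]
            gene_id = gene.gene_id
            true_tail = tail
            rec = _build_alignment(
                rid, gene, genome, 1, gene.mature_length, tail_seq, True, len(copies)
            )

        # --- library-preparation model (independent RNG stream, fixed draw count)
        u_end1, u_end2, u_methyl, u_amino, u_adapter = rng_clone.random(5)
        bad_ends = _bad_ends(cls, true_tail)
        drop = "none"
        if not cfg.pnk_treated:
            if (bad_ends >= 1 and u_end1 < cfg.p_end_fail) or (
                bad_ends >= 2 and u_end2 < cfg.p_end_fail
            ):
                drop = "end_chemistry"
        if drop == "none" and cls in ("5half", "3half") and not cfg.demethylated:
            if u_methyl < _methyl_prob(cfg.p_methyl_block, fam, cls[0]):
                drop = "methyl_block"
        if drop == "none" and not cfg.deacylated and cfg.p_aminoacyl > 0:
            if cls in ("full_length", "3half") and true_tail == "CCA" and u_amino < cfg.p_aminoacyl:
                drop = "aminoacyl"
        has_adapter = u_adapter >= cfg.frac_no_adapter
        cloned = drop == "none"

        if cloned:
            if not has_adapter:
                rec = replace(rec, has_adapter=False)
                raw = rand_ends[0] + rec.seq
            else:
                raw = rand_ends[0] + rec.seq + cfg.adapter + rand_ends[1]
            records.append(rec)
            raw_reads.append((rid, raw))

        truth_rows.append(
            {
                "read_id": rid,
                "family": fam,
                "gene_id": gene_id,
                "true_class": cls,
                "true_tail": true_tail,
                "length": len(rec.seq),
                "cloned": cloned,
                "drop_reason": drop,
                "has_adapter": has_adapter if cloned else True,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return SimResult(records=records, truth=truth, config=cfg, genome=genome, raw_reads=raw_reads)


def _bad_ends(cls: str, true_tail: str) -> int:
    """Number of unligatable (cyclic-phosphate / 5'-OH) ends per molecule class.

    A 3' half carries two cleaved ends when its CCA tail was also trimmed,
    one when the tail is intact; a 5' half always carries one (its cleaved
    3' end); full-length molecules carry one only if their tail was trimmed.
    Y fragments carry one cleaved end; backgrounds none.
    """
    if cls == "5half":
        return 1
    if cls == "3half":
        return 1 + (true_tail != "CCA")
    if cls == "full_length":
        return int(true_tail != "CCA")
    if cls in ("y5frag", "y3frag"):
        return 1
    return 0


_ALPH = np.array(list("ACGT"))


def _rand4(rng: np.random.Generator) -> str:
    return "".join(_ALPH[rng.integers(0, 4, 4)])
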