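"""Dataset-level summaries: half fraction, 5'/3' split, per-family tables,
imbalance statistics and length distributions.

Percentages mirror the conventions of descriptive extracellular-RNA reports:
the half fraction is computed over *all* mapped primary alignments (unique
reads plus one primary per multimapper), family tables are aggregated by
isoacceptor family (amino acid + anticodon) and half type, and replicate runs
are reported as mean +/- SD.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .classify import FragmentCall, Half, HalfWindows, tail_status_table

__all__ = [
    "RunConfig",
    "SummaryReport",
    "summarize",
    "summarize_replicates",
    "imbalance_stats",
    "top_table",
]


@dataclass(frozen=True)
class RunConfig:
    windows: HalfWindows = HalfWindows()
    adapter: str = "TGGAATTCTC"
    min_match: int = 6
    imbalance_threshold: float = 10.0
    min_group_halves: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imbalance_threshold <= 1:
            raise ValueError("imbalance_threshold must be > 1")
        if self.min_group_halves < 1:
            raise ValueError("min_group_halves must be >= 1")


@dataclass
class SummaryReport:
    n_mapped_primary: int
    n_qualified: int
    n_halves: int
    half_fraction: float
    split5: float
    split3: float
    tail_table: dict
    group_table: list[dict]
    imbalance: dict
    length_hist: dict[str, dict[int, int]]
    config: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        d = {
            "n_mapped_primary": self.n_mapped_primary,
            "n_qualified": self.n_qualified,
            "n_halves": self.n_halves,
            "half_fraction": self.half_fraction,
            "split5": self.split5,
            "split3": self.split3,
            "tail_table": self.tail_table,
            "group_table": self.group_table,
            "imbalance": self.imbalance,
            "length_hist": {k: dict(v) for k, v in self.length_hist.items()},
            "config": {
                "imbalance_threshold": self.config.imbalance_threshold,
                "min_group_halves": self.config.min_group_halves,
                "windows": vars(self.config.windows),
            },
        }
        return d


def _group_half_counts(calls) -> dict[str, tuple[int, int]]:
    """Per-identity-group (5' half count, 3' half count)."""
    c5: Counter = Counter()
    c3: Counter = Counter()
    for c in calls:
        if c.half == Half.FIVE_PRIME:
            c5[c.identity_group] += 1
        elif c.half == Half.THREE_PRIME:
            c3[c.identity_group] += 1
    return {g: (c5.get(g, 0), c3.get(g, 0)) for g in set(c5) | set(c3)}


def imbalance_stats(
    group_counts: dict[str, tuple[int, int]],
    threshold: float = 10.0,
    min_total: int = 10,
) -> dict:
    """Fraction of identity groups with a < threshold:1 imbalance between halves.

    Groups with fewer than ``min_total`` halves are excluded from the
    denominator.  A group with one half entirely absent has an infinite ratio
    and fails the threshold.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    table = {}
    below = 0
    considered = 0
    for g, (a, b) in group_counts.items():
        if a + b < min_total:
            continue
        considered += 1
        ratio = math.inf if min(a, b) == 0 else max(a, b) / min(a, b)
        ok = ratio < threshold
        below += ok
        table[g] = {"c5": a, "c3": b, "ratio": ratio, "below_threshold": ok}
    return {
        "per_group": table,
        "n_groups": considered,
        "pct_below_threshold": (100.0 * below / considered) if considered else math.nan,
    }


def summarize(
    calls: list[FragmentCall], n_mapped_primary: int, cfg: RunConfig = RunConfig()
) -> SummaryReport:
    """Summarize one replicate's fragment calls."""
    if n_mapped_primary < len(calls):
        raise ValueError("n_mapped_primary smaller than the number of qualified reads")
    n5 = sum(c.half == Half.FIVE_PRIME for c in calls)
    n3 = sum(c.half == Half.THREE_PRIME for c in calls)
    halves = n5 + n3
    half_fraction = halves / n_mapped_primary if n_mapped_primary else 0.0
    split5 = n5 / halves if halves else math.nan
    split3 = n3 / halves if halves else math.nan

    rows: Counter = Counter(
        (c.family, c.half) for c in calls if c.half != Half.OTHER
    )
    group_table = [
        {
            "family": fam,
            "half": half,
            "count": cnt,
            "pct_of_halves": 100.0 * cnt / halves,
        }
        for (fam, half), cnt in rows.items()
    ]
    group_table.sort(key=lambda r: (-r["count"], r["family"], r["half"]))

    length_hist: dict[str, Counter] = defaultdict(Counter)
    for c in calls:
        length_hist["all"][c.trimmed_length] += 1
        length_hist[c.half][c.trimmed_length] += 1

    imb = imbalance_stats(
        _group_half_counts(calls), cfg.imbalance_threshold, cfg.min_group_halves
    )
    return SummaryReport(
        n_mapped_primary=n_mapped_primary,
        n_qualified=len(calls),
        n_halves=halves,
        half_fraction=half_fraction,
        split5=split5,
        split3=split3,
        tail_table=tail_status_table(calls),
        group_table=group_table,
        imbalance=imb,
        length_hist={k: dict(sorted(v.items())) for k, v in length_hist.items()},
        config=cfg,
    )


def summarize_replicates(
    replicates: list[tuple[list[FragmentCall], int]], cfg: RunConfig = RunConfig()
) -> dict:
    """Mean +/- SD of the scalar metrics across replicate call sets.

    SDs are sample standard deviations (ddof=1); with a single replicate they
    are reported as None, not zero.
    """
    reports = [summarize(calls, n, cfg) for calls, n in replicates]

    def agg(values):
        arr = np.asarray(values, dtype=float)
        finite = arr[~np.isnan(arr)]
        mean = float(np.mean(finite)) if finite.size else math.nan
        sd = (
            float(np.std(finite, ddof=1))
            if len(arr) > 1 and finite.size > 1
            else None
        )
        return {"mean": mean, "sd": sd}

    out = {
        "n_replicates": len(reports),
        "half_fraction": agg([r.half_fraction for r in reports]),
        "split5": agg([r.split5 for r in reports]),
        "split3": agg([r.split3 for r in reports]),
        "tail_fractions": {
            t: agg([r.tail_table["fractions"][t] for r in reports])
            for t in ("NONE", "C", "CC", "CCA")
        },
        "replicates": [r.to_dict() for r in reports],
    }
    return out


def top_table(
    replicate_calls: list[list[FragmentCall]] | list[FragmentCall], k: int = 10
) -> list[dict]:
    """Most abundant (family, half-type) rows as % of all halves, mean +/- SD.

    Accepts a single call set or a list of replicate call sets.  Rows are
    sorted by mean percentage descending, ties broken lexicographically by
    (family, half).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if replicate_calls and isinstance(replicate_calls[0], FragmentCall):
        replicate_calls = [replicate_calls]

    per_rep: list[dict[tuple[str, str], float]] = []
    keys: set[tuple[str, str]] = set()
    for calls in replicate_calls:
        halves = [c for c in calls if c.half in (Half.FIVE_PRIME, Half.THREE_PRIME)]
        counts = Counter((c.family, c.half) for c in halves)
        total = len(halves)
        pct = {key: 100.0 * v / total for key, v in counts.items()} if total else {}
        per_rep.append(pct)
        keys |= set(pct)

    rows = []
    for key in keys:
        vals = [rep.get(key, 0.0) for rep in per_rep]
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        rows.append(
            {"family": key[0], "half": key[1], "pct_of_halves": mean, "sd": sd}
        )
    rows.sort(key=lambda r: (-r["pct_of_halves"], r["family"], r["half"]))
    return rows[:k]
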