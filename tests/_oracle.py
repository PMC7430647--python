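"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's CIGAR/coordinate machinery: the window
oracle is a literal transcription of the half-definition sentence with
explicit integer sets, and the read oracle re-derives qualification, tail and
half class purely by exact string matching of the read sequence against the
spliced gene sequence plus an optional C/CC/CCA tail.
"""

from __future__ import annotations

FIVE, THREE, OTHER = "5p", "3p", "other"


def window_oracle(tstart: int, tend: int, L: int) -> str:
    """Half class by literal enumeration of the stated windows."""
    starts5 = set(range(1, 6))            # "no farther than at the fifth nucleotide"
    loop = set(range(29, 42))             # "within nucleotides 29-41"
    last5 = set(range(L - 4, L + 1))      # "within the last five nucleotides"
    if tstart in starts5 and tend in loop:
        return FIVE
    if tstart in loop and tend in last5:
        return THREE
    return OTHER


def read_oracle(
    seq: str,
    mature: str,
    *,
    is_primary: bool = True,
    is_mito: bool = False,
    has_adapter: bool = True,
):
    """(reason, tail, half) by exhaustive string matching.

    A read is acceptable iff seq == mature[a-1:b] for some 1<=a<=b<=L, or
    seq == mature[a-1:L] + t for a 3'-reaching read with t in {C, CC, CCA}.
    Returns the set of admissible (tail, half) interpretations together with
    the reason; the set is empty when no placement exists.
    """
    if not is_primary:
        return "not_primary", set()
    if is_mito:
        return "mito", set()
    if not has_adapter:
        return "no_adapter", set()
    L = len(mature)
    hits = set()
    for a in range(1, L + 1):
        for b in range(a, L + 1):
            if seq == mature[a - 1 : b]:
                tail = "NONE" if b == L else "NOT_TAILED"
                hits.add((tail, window_oracle(a, b, L)))
            if b == L:
                for t in ("C", "CC", "CCA"):
                    if seq == mature[a - 1 :] + t:
                        hits.add((t, window_oracle(a, b, L)))
    if not hits:
        return "unplaceable", set()
    return "ok", hits
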