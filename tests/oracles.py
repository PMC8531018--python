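"""Independent brute-force oracles used only by the tests.

Each oracle is a from-first-principles reimplementation kept deliberately
naive and separate from the package code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


def orf_scan_oracle(seq: str) -> list[tuple[int, int, int, str]]:
    """Six-frame ORF scan: (frame, nt_start, nt_end, protein) tuples.

    Reimplements the rules directly: per frame, maximal stop-free codon
    stretches; the stretch before the first stop needs no ATG, stretches
    after a stop start at their first ATG; the terminal stop codon (when
    present) is part of the interval; codons with N give X.
    """
    out = []
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
        # indices of stop codons
        stops = [i for i, c in enumerate(codons) if c in _STOPS]
        boundaries = [-1] + stops  # segment i spans (boundaries[i], next stop)
        for seg_idx, lo in enumerate(boundaries):
            hi = stops[seg_idx] if seg_idx < len(stops) else len(codons)
            start = lo + 1
            if seg_idx > 0:  # downstream of a stop: need an ATG
                atg = [i for i in range(start, hi) if codons[i] == "ATG"]
                if not atg:
                    continue
                start = atg[0]
            if start >= hi:
                continue
            stopped = seg_idx < len(stops)
            protein = "".join(
                "X" if "N" in c else str(Seq(c).translate()) for c in codons[start:hi]
            )
            w_lo = off + 3 * start
            w_hi = off + 3 * (hi + (1 if stopped else 0))
            if frame > 0:
                out.append((frame, w_lo, w_hi, protein))
            else:
                out.append((frame, L - w_hi, L - w_lo, protein))
    return out


def components_oracle(edges, all_ids):
    """Connected components by iterated set merging (transitive closure)."""
    sets = [{i} for i in all_ids]
    for a, b in edges:
        sa = next(s for s in sets if a in s)
        sb = next(s for s in sets if b in s)
        if sa is not sb:
            sets.remove(sb)
            sa |= sb
    return {frozenset(s) for s in sets}


def hypergeom_upper_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total


def exact_membership_counts_oracle(sets: dict) -> dict[frozenset, int]:
    """Count union elements by their exact membership pattern."""
    names = sorted(sets)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for item in set().union(*sets.values()):
        counts[frozenset(n for n in names if item in sets[n])] += 1
    return counts
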