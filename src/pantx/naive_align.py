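"""A deliberately simple exact-k-mer chaining aligner.

This is not a Blat replacement: it exists so that fixtures and in-package
fallbacks can produce PSL-style hits for sequences whose true relationship is
known (exact or lightly mutated substrings, planted bridges). It seeds on
exact k-mers (default k=20), merges co-diagonal seeds into ungapped blocks,
and chains blocks colinearly with a tiny dynamic program. Substitutions
between blocks on one diagonal become mismatches; diagonal shifts become
gaps. N bases never count as matches.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from .io_model import AlignmentHit, Strand

DEFAULT_K = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seed_blocks(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal co-diagonal exact blocks as (q_start, t_start, length)."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(target) - k + 1):
        index[target[i : i + k]].append(i)
    # diagonal (t - q) -> sorted q positions of seed starts
    diag_hits: dict[int, set[int]] = defaultdict(set)
    for q in range(len(query) - k + 1):
        kmer = query[q : q + k]
        if "N" in kmer:
            continue
        for t in index.get(kmer, ()):
            diag_hits[t - q].add(q)
    blocks: list[tuple[int, int, int]] = []
    for diag, qset in diag_hits.items():
        qs = sorted(qset)
        start = qs[0]
        prev = qs[0]
        for q in qs[1:]:
            if q <= prev + k:  # overlapping/adjacent seeds extend the block
                prev = q
            else:
                blocks.append((start, start + diag, prev + k - start))
                start = prev = q
        blocks.append((start, start + diag, prev + k - start))
    blocks.sort()
    return blocks


def _chain(blocks: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear chain of blocks by total block length (O(n^2) DP)."""
    if not blocks:
        return []
    n = len(blocks)
    best = [b[2] for b in blocks]
    prev = [-1] * n
    for j in range(n):
        qj, tj, _ = blocks[j]
        for i in range(j):
            qi, ti, li = blocks[i]
            if qi + li <= qj and ti + li <= tj:
                cand = best[i] + blocks[j][2]
                if cand > best[j]:
                    best[j] = cand
                    prev[j] = i
    end = max(range(n), key=lambda j: best[j])
    chain = []
    while end != -1:
        chain.append(blocks[end])
        end = prev[end]
    return chain[::-1]


def _hit_from_chain(
    query: str,
    target: str,
    query_id: str,
    target_id: str,
    chain: list[tuple[int, int, int]],
    strand: Strand,
    query_len: int,
) -> AlignmentHit:
    matches = 0
    for q, t, l in chain:
        matches += sum(
            1 for a, b in zip(query[q : q + l], target[t : t + l]) if a == b and a != "N"
        )
    mismatches = 0
    q_gap_count = t_gap_count = q_gap_bases = t_gap_bases = 0
    for (q1, t1, l1), (q2, t2, _) in zip(chain, chain[1:]):
        qgap = q2 - (q1 + l1)
        tgap = t2 - (t1 + l1)
        mismatches += min(qgap, tgap)
        if qgap > tgap:
            q_gap_count += 1
            q_gap_bases += qgap - tgap
        elif tgap > qgap:
            t_gap_count += 1
            t_gap_bases += tgap - qgap
    q_start = chain[0][0]
    q_end = chain[-1][0] + chain[-1][2]
    t_start = chain[0][1]
    t_end = chain[-1][1] + chain[-1][2]
    if strand is Strand.REVERSE:
        # PSL convention: query coordinates stay on the forward strand.
        q_start, q_end = query_len - q_end, query_len - q_start
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        q_gap_count=q_gap_count,
        t_gap_count=t_gap_count,
        q_gap_bases=q_gap_bases,
        t_gap_bases=t_gap_bases,
    )


def align_pair(
    query_id: str,
    query_seq: str,
    target_id: str,
    target_seq: str,
    k: int = DEFAULT_K,
) -> list[AlignmentHit]:
    """Align one query against one target on both strands.

    Returns zero, one, or two hits (at most one per strand); a hit is emitted
    whenever at least one exact k-mer is shared.
    """
    hits = []
    for strand, qseq in (
        (Strand.FORWARD, query_seq),
        (Strand.REVERSE, revcomp(query_seq)),
    ):
        chain = _chain(_seed_blocks(qseq, target_seq, k))
        if chain:
            hits.append(
                _hit_from_chain(
                    qseq, target_seq, query_id, target_id, chain, strand,
                    len(query_seq),
                )
            )
    return hits


def align_all(
    queries: Iterable[tuple[str, str]],
    targets: Iterable[tuple[str, str]],
    k: int = DEFAULT_K,
    skip_self: bool = True,
) -> list[AlignmentHit]:
    """All-vs-all alignment of (id, seq) pairs; self-hits skipped by default."""
    targets = list(targets)
    hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        for tid, tseq in targets:
            if skip_self and qid == tid:
                continue
            hits.extend(align_pair(qid, qseq, tid, tseq, k=k))
    return hits
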