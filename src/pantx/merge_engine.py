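"""Unify two de novo transcriptome assemblies.

Every transcript of the query assembly is classified against the base
assembly using Blat-style alignment hits:

* ``UNIQUE`` — no hit reaches the minimum score; the transcript is added to
  the unified set (and later clustered into loci).
* ``MERGE`` — the transcript bridges two distinct base transcripts, one
  matched on the query's 5' side near that anchor's 3' end and one on the 3'
  side near the other anchor's 5' end: the three are merged into one longer
  transcript, with the base (anchor) sequence kept verbatim in the aligned
  regions.
* ``REDUNDANT`` — anything else: the query overlaps the base assembly and is
  dropped in favor of the base transcript(s).

Merging is checked before redundancy, and the base assembly's sequence is
always preferred where the two assemblies overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .io_model import (
    AlignmentHit,
    Category,
    NomenclatureCounters,
    Source,
    Strand,
    TranscriptRecord,
    assign_nomenclature,
    locus_of,
)
from .naive_align import align_all, revcomp


@dataclass
class MergeParams:
    """Thresholds of the two-anchor merge test.

    ``min_score``: minimum Blat score for a hit to count as overlap at all.
    ``max_gap_bases``: maximum internal alignment gap per anchor hit.
    ``max_end_overhang``: unmatched bases tolerated at each outer end of the
    merge (assembly ends are error-prone, so short overhangs are forgiven).
    ``manual_min_score``: score at which a manually curated gene displaces
    overlapping automatic transcripts.
    """

    min_score: int = 100
    max_gap_bases: int = 200
    max_end_overhang: int = 100
    manual_min_score: int = 200

    def __post_init__(self) -> None:
        for name in ("min_score", "max_gap_bases", "max_end_overhang", "manual_min_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class DecisionCategory(str, enum.Enum):
    UNIQUE = "UNIQUE"
    REDUNDANT = "REDUNDANT"
    MERGE = "MERGE"


@dataclass
class MergeDecision:
    query_id: str
    category: DecisionCategory
    anchor5_id: str | None = None
    anchor3_id: str | None = None
    supporting_hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class MergedPart:
    """Provenance of one segment of a merged transcript."""

    source_id: str
    source_interval: tuple[int, int]
    merged_interval: tuple[int, int]
    strand: Strand = Strand.FORWARD


@dataclass
class MergedTranscript:
    seq: str
    parts: list[MergedPart]
    name: str | None = None


def _oriented_query_hits(
    hits: list[AlignmentHit], query_len: int
) -> dict[int, AlignmentHit]:
    """Map id(hit) -> hit with query coordinates in aligned orientation.

    PSL keeps minus-strand query coordinates on the forward strand; the merge
    geometry reasons in the orientation in which the bridge aligns, so
    minus-strand hits get their query interval mirrored.
    """
    out = {}
    for h in hits:
        if h.strand is Strand.REVERSE:
            out[id(h)] = AlignmentHit(
                query_id=h.query_id, target_id=h.target_id, strand=h.strand,
                matches=h.matches, mismatches=h.mismatches,
                q_start=query_len - h.q_end, q_end=query_len - h.q_start,
                t_start=h.t_start, t_end=h.t_end,
                q_gap_count=h.q_gap_count, t_gap_count=h.t_gap_count,
                q_gap_bases=h.q_gap_bases, t_gap_bases=h.t_gap_bases,
            )
        else:
            out[id(h)] = h
    return out


def classify_query_transcript(
    query: TranscriptRecord,
    hits: list[AlignmentHit],
    params: MergeParams,
    target_lengths: dict[str, int],
    unavailable_anchors: frozenset[str] = frozenset(),
) -> MergeDecision:
    """Classify one query transcript as UNIQUE, MERGE, or REDUNDANT.

    ``target_lengths`` must cover every hit's target (a hit referencing an
    unknown base transcript is a hard error). ``unavailable_anchors`` lets a
    driving loop exclude already-consumed anchors from merge candidacy while
    still counting their hits as overlap.
    """
    for h in hits:
        if h.query_id != query.id:
            raise ValueError(f"hit query {h.query_id!r} does not match {query.id!r}")
        if h.target_id not in target_lengths:
            raise ValueError(f"hit references unknown base transcript {h.target_id!r}")

    passing = [h for h in hits if h.score >= params.min_score]
    if not passing:
        return MergeDecision(query.id, DecisionCategory.UNIQUE)

    qlen = len(query)
    oriented = _oriented_query_hits(passing, qlen)
    mergeable = [
        h
        for h in passing
        if h.gap_bases <= params.max_gap_bases and h.target_id not in unavailable_anchors
    ]

    best: tuple[int, str, str, AlignmentHit, AlignmentHit] | None = None
    for a in mergeable:
        for b in mergeable:
            if a.target_id == b.target_id:
                continue
            if a.strand is not b.strand:
                continue
            oa, ob = oriented[id(a)], oriented[id(b)]
            # a anchors the query 5' side, b the 3' side (aligned orientation)
            if not (oa.q_start < ob.q_start and oa.q_end < ob.q_end):
                continue
            # anchor A entered near its 3' end, anchor B near its 5' end
            if target_lengths[a.target_id] - oa.t_end > params.max_end_overhang:
                continue
            if ob.t_start > params.max_end_overhang:
                continue
            # outer query overhangs
            if oa.q_start > params.max_end_overhang:
                continue
            if qlen - ob.q_end > params.max_end_overhang:
                continue
            key = (a.score + b.score, a.target_id, b.target_id)
            if best is None or (key[0], ) > (best[0], ) or (
                key[0] == best[0] and (key[1], key[2]) < (best[1], best[2])
            ):
                best = (key[0], key[1], key[2], a, b)
    if best is not None:
        _, a5, a3, ha, hb = best
        return MergeDecision(
            query.id, DecisionCategory.MERGE,
            anchor5_id=a5, anchor3_id=a3, supporting_hits=[ha, hb],
        )
    return MergeDecision(query.id, DecisionCategory.REDUNDANT, supporting_hits=passing)


def build_merged_transcript(
    anchor5: TranscriptRecord,
    bridge: TranscriptRecord,
    anchor3: TranscriptRecord,
    hit5: AlignmentHit,
    hit3: AlignmentHit,
) -> MergedTranscript:
    """Merge anchor5 + bridge + anchor3 into one transcript.

    The merged sequence is ``anchor5[0:t_end5) + bridge[q_end5:q_start3) +
    anchor3[t_start3:)``; anchor sequence is kept verbatim in aligned
    regions. A minus-strand bridge is reverse-complemented first. When the
    two anchor hits overlap on the bridge, the bridge contributes nothing and
    the anchors are joined directly, provided their sequences agree across
    the junction.
    """
    if hit5.strand is not hit3.strand:
        raise ValueError("anchor hits on opposite strands cannot be merged")
    qlen = len(bridge)
    bridge_seq = bridge.seq
    bridge_strand = hit5.strand
    if bridge_strand is Strand.REVERSE:
        bridge_seq = revcomp(bridge_seq)
        oriented = _oriented_query_hits([hit5, hit3], qlen)
        hit5, hit3 = oriented[id(hit5)], oriented[id(hit3)]

    t_end5, q_end5 = hit5.t_end, hit5.q_end
    q_start3, t_start3 = hit3.q_start, hit3.t_start

    parts: list[MergedPart] = []
    pieces: list[str] = []
    cursor = 0

    def _add(source: TranscriptRecord, lo: int, hi: int, strand: Strand, seq: str) -> None:
        nonlocal cursor
        if hi <= lo:
            return
        pieces.append(seq)
        parts.append(
            MergedPart(
                source_id=source.id,
                source_interval=(lo, hi),
                merged_interval=(cursor, cursor + (hi - lo)),
                strand=strand,
            )
        )
        cursor += hi - lo

    _add(anchor5, 0, t_end5, Strand.FORWARD, anchor5.seq[:t_end5])

    if q_end5 <= q_start3:
        if bridge_strand is Strand.REVERSE:
            # record provenance on the original (forward) bridge coordinates
            lo, hi = qlen - q_start3, qlen - q_end5
            _add(bridge, lo, hi, Strand.REVERSE, bridge_seq[q_end5:q_start3])
        else:
            _add(bridge, q_end5, q_start3, Strand.FORWARD, bridge_seq[q_end5:q_start3])
        a3_from = t_start3
    else:
        overlap = q_end5 - q_start3
        if (
            overlap > t_end5
            or overlap > len(anchor3) - t_start3
            or anchor5.seq[t_end5 - overlap : t_end5]
            != anchor3.seq[t_start3 : t_start3 + overlap]
        ):
            raise ValueError(
                f"incompatible merge: anchors {anchor5.id}/{anchor3.id} disagree "
                f"over a {overlap} bp junction overlap"
            )
        a3_from = t_start3 + overlap

    _add(anchor3, a3_from, len(anchor3), Strand.FORWARD, anchor3.seq[a3_from:])

    seq = "".join(pieces)
    if len(seq) < max(len(anchor5), len(anchor3)):
        raise ValueError("merged transcript shorter than an anchor; geometry invalid")
    return MergedTranscript(seq=seq, parts=parts)


def integrate_manual_genes(
    unified: list[TranscriptRecord],
    manual: list[TranscriptRecord],
    hits: list[AlignmentHit],
    params: MergeParams,
    counters: NomenclatureCounters | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], list[tuple[str, str]]]:
    """Fold manually curated genes into the unified set.

    Any automatic transcript with a hit of score >= ``manual_min_score`` to a
    manual gene is discarded (logged as ``(auto_id, manual_id)``); the manual
    genes are appended under the manual naming range.
    """
    if counters is None:
        counters = NomenclatureCounters()
    manual_ids = {m.id for m in manual}
    displaced: dict[str, str] = {}
    for h in hits:
        if h.score < params.manual_min_score:
            continue
        if h.query_id in manual_ids and h.target_id not in manual_ids:
            displaced.setdefault(h.target_id, h.query_id)
        elif h.target_id in manual_ids and h.query_id not in manual_ids:
            displaced.setdefault(h.query_id, h.target_id)
    kept = [r for r in unified if r.id not in displaced]
    discard_log = sorted(displaced.items())
    named_manual, _ = assign_nomenclature(
        [TranscriptRecord(id=m.id, seq=m.seq, source=Source.MANUAL) for m in manual],
        Category.MANUAL,
        counters,
    )
    return kept, named_manual, discard_log


@dataclass
class UnifyResult:
    records: list[TranscriptRecord]
    decisions: list[MergeDecision]
    merged: list[MergedTranscript]
    discard_log: list[tuple[str, str]]
    id_map: dict[str, str]

    def decision_counts(self) -> dict[str, int]:
        counts = {c.value: 0 for c in DecisionCategory}
        for d in self.decisions:
            counts[d.category.value] += 1
        return counts


def unify(
    base: list[TranscriptRecord],
    query: list[TranscriptRecord],
    base_query_hits: list[AlignmentHit],
    manual: list[TranscriptRecord] | None = None,
    manual_hits: list[AlignmentHit] | None = None,
    params: MergeParams | None = None,
    query_self_hits: list[AlignmentHit] | None = None,
    cluster_params: "ClusterParams | None" = None,
) -> UnifyResult:
    """Run the full unification pipeline.

    Output = base transcripts (minus merge anchors and manually displaced
    records) + merged transcripts + unique query transcripts clustered into
    loci + manual genes, with a decision log holding exactly one entry per
    query transcript. ``query_self_hits`` (all-vs-all hits among the added
    transcripts, used for locus clustering) is computed with the built-in
    k-mer aligner when not supplied.
    """
    from .locus_clustering import ClusterParams, cluster_added

    params = params or MergeParams()
    counters = NomenclatureCounters()

    all_ids = [r.id for r in base] + [r.id for r in query] + [
        m.id for m in (manual or [])
    ]
    if len(set(all_ids)) != len(all_ids):
        dupes = sorted({i for i in all_ids if all_ids.count(i) > 1})
        raise ValueError(f"transcript ids not distinct across inputs: {dupes}")

    base_by_id = {r.id: r for r in base}
    query_by_id = {r.id: r for r in query}
    target_lengths = {r.id: len(r) for r in base}
    hits_by_query: dict[str, list[AlignmentHit]] = {q.id: [] for q in query}
    for h in base_query_hits:
        if h.query_id not in query_by_id:
            raise ValueError(f"hit references unknown query transcript {h.query_id!r}")
        hits_by_query[h.query_id].append(h)

    decisions: list[MergeDecision] = []
    merged_transcripts: list[MergedTranscript] = []
    merged_records: list[TranscriptRecord] = []
    consumed_anchors: set[str] = set()
    unique_records: list[TranscriptRecord] = []
    id_map: dict[str, str] = {}

    for q in query:
        decision = classify_query_transcript(
            q, hits_by_query[q.id], params, target_lengths,
            unavailable_anchors=frozenset(consumed_anchors),
        )
        decisions.append(decision)
        if decision.category is DecisionCategory.MERGE:
            hit5, hit3 = decision.supporting_hits
            mt = build_merged_transcript(
                base_by_id[decision.anchor5_id], q, base_by_id[decision.anchor3_id],
                hit5, hit3,
            )
            named, mapping = assign_nomenclature(
                [TranscriptRecord(id=q.id, seq=mt.seq, source=Source.MERGED)],
                Category.MERGED,
                counters,
            )
            mt.name = named[0].id
            id_map.update(mapping)
            merged_transcripts.append(mt)
            merged_records.extend(named)
            consumed_anchors.update({decision.anchor5_id, decision.anchor3_id})
        elif decision.category is DecisionCategory.UNIQUE:
            unique_records.append(q)

    if unique_records:
        if query_self_hits is None:
            pairs = [(r.id, r.seq) for r in unique_records]
            query_self_hits = align_all(pairs, pairs, skip_self=True)
        added_records, added_map = cluster_added(
            unique_records, query_self_hits, counters,
            params=cluster_params or ClusterParams(),
        )
        id_map.update(added_map)
    else:
        added_records = []

    kept_base = [
        TranscriptRecord(
            id=r.id, seq=r.seq, source=r.source, locus_id=r.locus_id or locus_of(r.id)
        )
        for r in base
        if r.id not in consumed_anchors
    ]
    automatic = kept_base + merged_records + added_records

    if manual:
        automatic, named_manual, discard_log = integrate_manual_genes(
            automatic, manual, manual_hits or [], params, counters
        )
        records = automatic + named_manual
    else:
        discard_log = []
        records = automatic

    return UnifyResult(
        records=records,
        decisions=decisions,
        merged=merged_transcripts,
        discard_log=discard_log,
        id_map=id_map,
    )
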