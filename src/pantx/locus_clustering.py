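"""Single-linkage clustering of added transcripts into loci.

Reproduces BLASTClust-style grouping: two transcripts are linked when some
pairwise hit has at least 95% identity over a region covering at least 20%
of the length of *both* members; loci are the connected components of the
link graph. Coverage is evaluated per hit (multiple partial hits between one
pair are not summed), and identity is ``matches / (matches + mismatches)``
with gap bases excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_model import (
    AlignmentHit,
    Category,
    NomenclatureCounters,
    TranscriptRecord,
    assign_nomenclature,
)


@dataclass
class ClusterParams:
    min_identity: float = 0.95
    min_coverage_both: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage_both"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class LocusCluster:
    locus_id: str
    member_ids: list[str]
    representative_id: str


def pair_links(
    hits: Iterable[AlignmentHit],
    lengths: Mapping[str, int],
    params: ClusterParams | None = None,
) -> list[tuple[str, str]]:
    """Undirected edges between transcripts that satisfy the link criteria.

    The aligned span is measured on each member separately: ``q_end-q_start``
    on the query and ``t_end-t_start`` on the target, each of which must
    cover at least ``min_coverage_both`` of that member's length.
    """
    params = params or ClusterParams()
    edges: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_id == h.target_id:
            continue
        for tid in (h.query_id, h.target_id):
            if tid not in lengths:
                raise ValueError(f"hit references unknown transcript {tid!r}")
        if h.identity < params.min_identity:
            continue
        if h.q_span < params.min_coverage_both * lengths[h.query_id]:
            continue
        if h.t_span < params.min_coverage_both * lengths[h.target_id]:
            continue
        edges.add((min(h.query_id, h.target_id), max(h.query_id, h.target_id)))
    return sorted(edges)


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def single_linkage(
    edges: Iterable[tuple[str, str]],
    all_ids: Sequence[str],
    lengths: Mapping[str, int] | None = None,
) -> list[list[str]]:
    """Connected components of the link graph, singletons included.

    Components are returned in order of each component's first member in
    ``all_ids``, with members in ``all_ids`` order — deterministic for a
    given input order and invariant to the order of the edge list.
    """
    uf = _UnionFind(all_ids)
    for a, b in edges:
        if a not in uf.parent or b not in uf.parent:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown id")
        uf.union(a, b)
    components: dict[str, list[str]] = {}
    order: list[str] = []
    for i in all_ids:
        root = uf.find(i)
        if root not in components:
            components[root] = []
            order.append(root)
        components[root].append(i)
    return [components[r] for r in order]


def make_clusters(
    components: Iterable[list[str]],
    lengths: Mapping[str, int],
    counters: NomenclatureCounters,
    category: Category = Category.ADDED_UNIQUE,
) -> list[LocusCluster]:
    """Name components in the given range; representative = longest member
    (ties broken by lexicographically smallest id)."""
    clusters = []
    for members in components:
        locus_id = counters.allocate_locus(category)
        rep = min(members, key=lambda m: (-lengths[m], m))
        clusters.append(
            LocusCluster(locus_id=locus_id, member_ids=list(members), representative_id=rep)
        )
    return clusters


def cluster_added(
    records: list[TranscriptRecord],
    hits: list[AlignmentHit],
    counters: NomenclatureCounters,
    params: ClusterParams | None = None,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Cluster added transcripts into loci and rename them accordingly.

    Returns renamed records (isoforms ``_seq1..`` in input order within each
    locus) and the old->new id mapping.
    """
    lengths = {r.id: len(r) for r in records}
    by_id = {r.id: r for r in records}
    edges = pair_links(hits, lengths, params)
    components = single_linkage(edges, [r.id for r in records])
    loci = [[by_id[m] for m in comp] for comp in components]
    return assign_nomenclature(loci, Category.ADDED_UNIQUE, counters)
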