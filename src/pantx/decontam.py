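"""Contamination screening of the unified transcriptome.

A representative transcript is kept when its best homology hit is the
organism itself or one of a small list of trusted relatives; otherwise it is
removed when a foreign hit is near-identical at the protein level
(criterion 1), near-identical and long at the nucleotide level
(criterion 2), or when the transcript is short and matches none of the
trusted taxa at all (criterion 3). Removal cascades from a locus
representative to all isoforms of its locus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_model import TranscriptRecord

#: Organism-name prefixes trusted as non-contaminant.
DEFAULT_ALLOWED_TAXA = (
    "Emiliania huxleyi",
    "Seriola lalandi dorsalis",
    "Chrysochromulina",
    "Aureococcus",
    "Guillardia theta",
)


@dataclass
class DecontamParams:
    allowed_taxa: tuple[str, ...] = DEFAULT_ALLOWED_TAXA
    protein_sim_cut: float = 0.95
    nt_ident_cut: float = 0.95
    nt_cov_cut: float = 0.50
    short_len_cut: int = 350  # strictly-below removal

    def __post_init__(self) -> None:
        for name in ("protein_sim_cut", "nt_ident_cut", "nt_cov_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


class HitKind(str, enum.Enum):
    PROTEIN = "PROTEIN"
    NUCLEOTIDE = "NUCLEOTIDE"


@dataclass
class TaxHit:
    """One taxon-annotated homology hit (BlastX or BlastN)."""

    query_id: str
    subject_taxon: str
    kind: HitKind
    similarity_or_identity: float
    query_coverage: float
    rank: int = 1


class Verdict(str, enum.Enum):
    KEEP = "KEEP"
    REMOVE_PROTEIN = "REMOVE_PROTEIN_SIMILARITY"
    REMOVE_NUCLEOTIDE = "REMOVE_NUCLEOTIDE_IDENTITY"
    REMOVE_SHORT = "REMOVE_SHORT_ORPHAN"


def is_allowed_taxon(taxon: str, params: DecontamParams) -> bool:
    """Case-insensitive prefix match against the trusted-taxa list."""
    t = taxon.lower()
    return any(t.startswith(p.lower()) for p in params.allowed_taxa)


def screen_transcript(
    rep: TranscriptRecord,
    hits: Sequence[TaxHit],
    params: DecontamParams | None = None,
) -> Verdict:
    """Decide KEEP/REMOVE for one representative transcript.

    ``hits`` must be sorted by rank (best first); an empty list is allowed.
    The best hit being a trusted taxon always keeps the transcript; otherwise
    any foreign hit can trigger removal under criteria 1-2, and short
    transcripts with no trusted hit anywhere are removed as orphans.
    """
    params = params or DecontamParams()
    has_allowed = any(is_allowed_taxon(h.subject_taxon, params) for h in hits)
    if hits and is_allowed_taxon(hits[0].subject_taxon, params):
        return Verdict.KEEP
    for h in hits:
        if is_allowed_taxon(h.subject_taxon, params):
            continue
        if h.kind is HitKind.PROTEIN and h.similarity_or_identity >= params.protein_sim_cut:
            return Verdict.REMOVE_PROTEIN
        if (
            h.kind is HitKind.NUCLEOTIDE
            and h.similarity_or_identity >= params.nt_ident_cut
            and h.query_coverage >= params.nt_cov_cut
        ):
            return Verdict.REMOVE_NUCLEOTIDE
    if len(rep) < params.short_len_cut and not has_allowed:
        return Verdict.REMOVE_SHORT
    return Verdict.KEEP


@dataclass
class RemovalLogEntry:
    transcript_id: str
    locus_id: str
    reason: Verdict


def cascade_removal(
    verdicts: Mapping[str, Verdict],
    records: list[TranscriptRecord],
    locus_of_rep: Mapping[str, str],
    locus_members: Mapping[str, Sequence[str]],
) -> tuple[list[TranscriptRecord], list[RemovalLogEntry]]:
    """Remove every isoform of each locus whose representative was removed.

    ``verdicts`` maps representative ids to their screening verdicts;
    ``locus_of_rep`` maps representative -> locus and ``locus_members``
    locus -> all member transcript ids. Returns the cleaned transcriptome
    and a removal log of (transcript, locus, reason).
    """
    removed: dict[str, RemovalLogEntry] = {}
    for rep_id, verdict in verdicts.items():
        if verdict is Verdict.KEEP:
            continue
        if rep_id not in locus_of_rep:
            raise ValueError(f"representative {rep_id!r} has no locus assignment")
        locus = locus_of_rep[rep_id]
        for member in locus_members[locus]:
            removed[member] = RemovalLogEntry(member, locus, verdict)
    cleaned = [r for r in records if r.id not in removed]
    log = [removed[r.id] for r in records if r.id in removed]
    return cleaned, log


def screen_transcriptome(
    records: list[TranscriptRecord],
    hits_by_query: Mapping[str, Sequence[TaxHit]],
    locus_of_rep: Mapping[str, str],
    locus_members: Mapping[str, Sequence[str]],
    params: DecontamParams | None = None,
) -> tuple[list[TranscriptRecord], list[RemovalLogEntry]]:
    """Screen every representative and cascade removals to isoforms."""
    params = params or DecontamParams()
    by_id = {r.id: r for r in records}
    verdicts = {
        rep_id: screen_transcript(
            by_id[rep_id],
            sorted(hits_by_query.get(rep_id, ()), key=lambda h: h.rank),
            params,
        )
        for rep_id in locus_of_rep
    }
    return cascade_removal(verdicts, records, locus_of_rep, locus_members)
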