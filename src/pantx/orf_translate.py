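"""Homology-guided ORF calling, non-coding candidate flagging, and chimera
splitting.

Each representative transcript is translated in all six frames to enumerate
candidate ORFs (maximal stop-free codon stretches). The frame actually
translated is chosen by a vote among the transcript's top three BlastX-style
protein hits; with no majority all hit frames are checked, and with no hits
at all the globally longest ORF wins. A methionine start is not required
unless an in-frame stop lies upstream, in which case the ORF starts at the
first ATG after that stop. Proteins shorter than 50 amino acids mark the
transcript as a non-coding candidate (plastid transcripts exempt).

Long transcripts whose longest ORF covers only a minority of their length
are screened as potential chimeras — single assembly artifacts fusing two or
three genes — and split between their long, non-overlapping ORFs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_model import ProteinHit, TranscriptRecord
from .naive_align import revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code (id 1), DNA codons.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def translate_codon(codon: str) -> str:
    """Translate one DNA codon; any codon containing N becomes X."""
    if "N" in codon:
        return "X"
    return _CODON_TABLE[codon]


@dataclass
class OrfParams:
    min_protein_aa: int = 50
    chimera_min_len: int = 2000
    chimera_orf_frac: float = 0.80
    chimera_min_protein_aa: int = 300
    chimera_max_parts: int = 3
    genetic_code: int = 1
    plastid_whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.genetic_code != 1:
            raise ValueError("only the standard genetic code (1) is supported")
        for name in ("min_protein_aa", "chimera_min_len", "chimera_min_protein_aa",
                     "chimera_max_parts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Orf:
    """One candidate ORF; coordinates are 0-based half-open on the forward
    strand regardless of frame sign, and include the terminal stop codon when
    one is present."""

    frame: int
    nt_start: int
    nt_end: int
    protein: str
    includes_stop: bool

    @property
    def protein_len(self) -> int:
        return len(self.protein)

    @property
    def nt_span(self) -> int:
        return self.nt_end - self.nt_start


class Evidence(str, enum.Enum):
    BLAST_VOTE = "BLAST_VOTE"
    BLAST_LONGEST_MATCHING = "BLAST_LONGEST_MATCHING"
    LONGEST_ORF = "LONGEST_ORF"


@dataclass
class OrfCall:
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str
    evidence: Evidence
    coding: bool


def _orfs_one_frame(working: str, frame: int, seq_len: int) -> list[Orf]:
    """ORFs of one frame; ``working`` is the strand read by that frame."""
    offset = abs(frame) - 1
    n_codons = (len(working) - offset) // 3
    if n_codons <= 0:
        return []
    aas = []
    for c in range(n_codons):
        p = offset + 3 * c
        aas.append(translate_codon(working[p : p + 3]))

    orfs: list[Orf] = []

    def _emit(start_codon: int, end_codon: int, stopped: bool) -> None:
        # codon interval [start_codon, end_codon) of protein, stop appended
        protein = "".join(aas[start_codon:end_codon])
        if not protein:
            return
        w_start = offset + 3 * start_codon
        w_end = offset + 3 * (end_codon + (1 if stopped else 0))
        if frame > 0:
            nt_start, nt_end = w_start, w_end
        else:
            nt_start, nt_end = seq_len - w_end, seq_len - w_start
        orfs.append(Orf(frame, nt_start, nt_end, protein, stopped))

    seg_start = 0  # first codon of the current stop-free segment
    after_stop = False
    c = 0
    while c < len(aas):
        if aas[c] == "*":
            if not after_stop:
                _emit(seg_start, c, True)
            else:
                # segment after an upstream stop: ORF starts at the first ATG
                m = next(
                    (i for i in range(seg_start, c)
                     if working[offset + 3 * i : offset + 3 * i + 3] == "ATG"),
                    None,
                )
                if m is not None:
                    _emit(m, c, True)
            after_stop = True
            seg_start = c + 1
        c += 1
    # trailing segment without a stop
    if seg_start < len(aas):
        if not after_stop:
            _emit(seg_start, len(aas), False)
        else:
            m = next(
                (i for i in range(seg_start, len(aas))
                 if working[offset + 3 * i : offset + 3 * i + 3] == "ATG"),
                None,
            )
            if m is not None:
                _emit(m, len(aas), False)
    return orfs


def find_orfs_six_frame(seq: str) -> list[Orf]:
    """Enumerate candidate ORFs in all six frames.

    Per frame, the maximal stop-free codon stretches are returned; the first
    stretch may start at the frame's first codon without a methionine, while
    stretches downstream of an in-frame stop start at their first ATG (and
    are dropped if they have none). Codons containing N translate to X.
    Sequences shorter than one codon yield an empty list.
    """
    if len(seq) < 3:
        return []
    rc = revcomp(seq)
    orfs: list[Orf] = []
    for frame in FRAME_ORDER:
        working = seq if frame > 0 else rc
        orfs.extend(_orfs_one_frame(working, frame, len(seq)))
    return orfs


# ---------------------------------------------------------------------------
# Frame voting and ORF calling
# ---------------------------------------------------------------------------

class VoteStatus(str, enum.Enum):
    VOTE = "VOTE"
    NO_MAJORITY = "NO_MAJORITY"
    NO_HITS = "NO_HITS"


@dataclass
class FrameVote:
    status: VoteStatus
    frame: int | None = None
    coords: tuple[int, int] | None = None  # union of agreeing hits' intervals


def vote_frame(hits: Sequence[ProteinHit]) -> FrameVote:
    """Majority vote on the reading frame among the top (up to 3) hits.

    A single hit is a trivial majority; three mutually different frames give
    NO_MAJORITY; no hits give NO_HITS.
    """
    top = sorted(hits, key=lambda h: h.rank)[:3]
    if not top:
        return FrameVote(VoteStatus.NO_HITS)
    by_frame: dict[int, list[ProteinHit]] = {}
    for h in top:
        by_frame.setdefault(h.frame, []).append(h)
    frame, agreeing = max(by_frame.items(), key=lambda kv: len(kv[1]))
    needed = 2 if len(top) > 1 else 1
    if len(agreeing) >= needed:
        coords = (min(h.q_start for h in agreeing), max(h.q_end for h in agreeing))
        return FrameVote(VoteStatus.VOTE, frame=frame, coords=coords)
    return FrameVote(VoteStatus.NO_MAJORITY)


def _overlaps(orf: Orf, interval: tuple[int, int]) -> bool:
    return orf.nt_start < interval[1] and interval[0] < orf.nt_end


def _best(orfs: Iterable[Orf]) -> Orf | None:
    """Longest protein; ties by smaller start, then frame order."""
    ranked = sorted(
        orfs,
        key=lambda o: (-o.protein_len, o.nt_start, FRAME_ORDER.index(o.frame)),
    )
    return ranked[0] if ranked else None


def call_orf(
    transcript: TranscriptRecord,
    hits: Sequence[ProteinHit],
    params: OrfParams | None = None,
) -> OrfCall:
    """Choose the ORF to translate for one transcript.

    With a frame majority among the top three protein hits, the longest ORF
    in that frame overlapping the voted coordinates is chosen (BLAST_VOTE);
    with no majority, the longest ORF in any hit frame overlapping that
    hit's coordinates (BLAST_LONGEST_MATCHING); with no hits, the globally
    longest ORF (LONGEST_ORF). Each stage falls through to the next when it
    finds no matching ORF. The call is flagged non-coding when the protein is
    shorter than ``min_protein_aa`` and the transcript is not plastid.
    """
    params = params or OrfParams()
    orfs = find_orfs_six_frame(transcript.seq)
    top = sorted(hits, key=lambda h: h.rank)[:3]
    vote = vote_frame(top)

    chosen: Orf | None = None
    evidence = Evidence.LONGEST_ORF
    if vote.status is VoteStatus.VOTE:
        chosen = _best(
            o for o in orfs if o.frame == vote.frame and _overlaps(o, vote.coords)
        )
        if chosen is not None:
            evidence = Evidence.BLAST_VOTE
    if chosen is None and top:
        chosen = _best(
            o
            for o in orfs
            if any(o.frame == h.frame and _overlaps(o, (h.q_start, h.q_end)) for h in top)
        )
        if chosen is not None:
            evidence = Evidence.BLAST_LONGEST_MATCHING
    if chosen is None:
        chosen = _best(orfs)
        evidence = Evidence.LONGEST_ORF

    if chosen is None:  # no ORF at all (e.g. sub-codon sequence)
        return OrfCall(transcript.id, 1, 0, 0, "", Evidence.LONGEST_ORF, coding=False)

    coding = (
        chosen.protein_len >= params.min_protein_aa
        or transcript.id in params.plastid_whitelist
    )
    return OrfCall(
        transcript_id=transcript.id,
        frame=chosen.frame,
        nt_start=chosen.nt_start,
        nt_end=chosen.nt_end,
        protein=chosen.protein,
        evidence=evidence,
        coding=coding,
    )


# ---------------------------------------------------------------------------
# Chimera splitting
# ---------------------------------------------------------------------------

def is_chimera_candidate(
    transcript: TranscriptRecord, orfs: Sequence[Orf], params: OrfParams
) -> bool:
    if len(transcript) <= params.chimera_min_len:
        return False
    longest = max((o.nt_span for o in orfs), default=0)
    return longest < params.chimera_orf_frac * len(transcript)


def split_chimeras(
    transcript: TranscriptRecord,
    orfs: Sequence[Orf],
    params: OrfParams | None = None,
) -> list[TranscriptRecord]:
    """Split a candidate chimera between its long, non-overlapping ORFs.

    The three best ORFs (by protein length) are considered; those of at
    least ``chimera_min_protein_aa`` whose nucleotide intervals do not
    mutually overlap are retained greedily by descending length. With two or
    three survivors the transcript is cut at the midpoints between adjacent
    ORF intervals, so the parts concatenate back to the original sequence;
    otherwise the transcript is returned unchanged.
    """
    params = params or OrfParams()
    if not is_chimera_candidate(transcript, orfs, params):
        return [transcript]
    best3 = sorted(
        orfs, key=lambda o: (-o.protein_len, o.nt_start, FRAME_ORDER.index(o.frame))
    )[: params.chimera_max_parts]
    survivors: list[Orf] = []
    for o in best3:
        if o.protein_len < params.chimera_min_protein_aa:
            continue
        if any(_overlaps(o, (s.nt_start, s.nt_end)) for s in survivors):
            continue
        survivors.append(o)
    if len(survivors) < 2:
        return [transcript]
    survivors.sort(key=lambda o: o.nt_start)
    cuts = [0]
    for prev, nxt in zip(survivors, survivors[1:]):
        cuts.append((prev.nt_end + nxt.nt_start) // 2)
    cuts.append(len(transcript))
    parts = []
    for i, (lo, hi) in enumerate(zip(cuts, cuts[1:]), start=1):
        parts.append(
            replace(
                transcript,
                id=f"{transcript.id}_split{i}",
                seq=transcript.seq[lo:hi],
            )
        )
    return parts


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class TranslationResult:
    calls: list[OrfCall]
    noncoding_ids: list[str]
    splits: dict[str, list[TranscriptRecord]] = field(default_factory=dict)

    @property
    def proteins(self) -> list[OrfCall]:
        return [c for c in self.calls if c.coding and c.protein]


def translate_transcriptome(
    records: list[TranscriptRecord],
    hits_by_query: Mapping[str, Sequence[ProteinHit]],
    params: OrfParams | None = None,
) -> TranslationResult:
    """Call ORFs for every representative, splitting chimeras first.

    A transcript that splits is replaced by its parts, each translated from
    its own surviving ORF segment; everything else goes through the
    homology-guided single-ORF call.
    """
    params = params or OrfParams()
    calls: list[OrfCall] = []
    noncoding: list[str] = []
    splits: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        orfs = find_orfs_six_frame(rec.seq)
        parts = split_chimeras(rec, orfs, params)
        if len(parts) > 1:
            splits[rec.id] = parts
            for part in parts:
                calls.append(call_orf(part, hits_by_query.get(part.id, ()), params))
        else:
            call = call_orf(rec, hits_by_query.get(rec.id, ()), params)
            calls.append(call)
            if not call.coding:
                noncoding.append(rec.id)
    return TranslationResult(calls=calls, noncoding_ids=noncoding, splits=splits)
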