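"""Domain types, file format readers/writers, and the locus/isoform
nomenclature engine.

Internal conventions, applied everywhere in the package:

* all coordinates are 0-based half-open; conversions happen only at file
  boundaries (PSL is natively 0-based half-open, tabular BLAST and VCF are
  1-based);
* alignment score follows the Blat web-score formula
  ``matches - mismatches - qNumInsert - tNumInsert``;
* identity is ``matches / (matches + mismatches)`` (gap bases excluded from
  the denominator);
* FASTA output wraps at 60 columns.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_LINE_WIDTH = 60

_VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")
_TRINITY_ID_RE = re.compile(r"^comp(\d+)_c(\d+)_seq(\d+)$")


class Source(str, enum.Enum):
    """Provenance of a transcript in the unified set."""

    BASE = "BASE"
    QUERY = "QUERY"
    MERGED = "MERGED"
    MANUAL = "MANUAL"


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass
class TranscriptRecord:
    """One assembled transcript.

    ``locus_id`` is the Trinity-style ``comp<N>_c<M>`` gene-level grouping;
    for auto-named records it is a prefix of ``id``.
    """

    id: str
    seq: str
    source: Source = Source.BASE
    locus_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"empty sequence for transcript {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One pairwise DNA alignment (Blat/BLAST style) between two transcripts.

    Coordinates are 0-based half-open on query and target; for minus-strand
    hits the query coordinates stay in forward orientation (PSL convention).
    """

    query_id: str
    target_id: str
    strand: Strand
    matches: int
    mismatches: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    q_gap_count: int = 0
    t_gap_count: int = 0
    q_gap_bases: int = 0
    t_gap_bases: int = 0

    @property
    def score(self) -> int:
        return self.matches - self.mismatches - self.q_gap_count - self.t_gap_count

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches
        return self.matches / denom if denom else 0.0

    @property
    def gap_bases(self) -> int:
        """Total internal gap bases of the alignment (both sides)."""
        return self.q_gap_bases + self.t_gap_bases

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start


@dataclass
class ProteinHit:
    """One ranked protein-homology (BlastX-style) hit for a transcript.

    ``frame`` follows BLAST convention (+1..+3 forward, -1..-3 on the
    reverse complement); query coordinates are nucleotide positions on the
    forward strand, 0-based half-open.
    """

    query_id: str
    rank: int
    frame: int
    q_start: int
    q_end: int
    subject_id: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if not self.q_start < self.q_end:
            raise ValueError("q_start must be < q_end")


@dataclass
class VariantRecord:
    """One VCF row restricted to the fields the hard filters consume."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    info: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class SampleMeta:
    sample_id: str
    strain: str
    timepoint: str
    replicate: str = "A"


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of normalized read counts with sample metadata."""

    genes: list[str]
    samples: list[SampleMeta]
    values: "np.ndarray"

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


import numpy as np  # noqa: E402  (needed by ExpressionMatrix at runtime)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, source: Source = Source.BASE) -> list[TranscriptRecord]:
    """Read a transcript FASTA into :class:`TranscriptRecord` objects.

    Sequences are uppercased and U is converted to T. The id is the first
    whitespace-delimited token of the header. Duplicate ids, empty sequences
    and characters outside ``{A,C,G,T,N,U}`` (any case) are hard errors.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        if not _VALID_SEQ_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(
                f"invalid characters in record {rec.id!r}: {', '.join(bad)}"
            )
        records.append(TranscriptRecord(id=rec.id, seq=seq, source=source))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at :data:`FASTA_LINE_WIDTH` columns."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=FASTA_LINE_WIDTH)
    writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# PSL (Blat native output, 21 columns)
# ---------------------------------------------------------------------------

_PSL_COLUMNS = 21

PSL_HEADER = (
    "psLayout version 3\n"
    "\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     "
    "\tsize\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    "---------------------------------------------------------------"
    "------------------------------------------------------------------\n"
)


def parse_psl(path: str | Path) -> list[AlignmentHit]:
    """Parse a 21-column PSL file (header optional) into alignment hits.

    The Blat web score ``matches - misMatches - qNumInsert - tNumInsert`` is
    exposed via :attr:`AlignmentHit.score`; PSL's native 0-based half-open
    coordinates are kept as-is.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            stripped = line.strip()
            if not stripped or not stripped[0].isdigit():
                continue  # blank or header line (psLayout banner, captions, dashes)
            fields = line.split("\t")
            if len(fields) != _PSL_COLUMNS:
                raise ValueError(
                    f"PSL line {lineno}: expected {_PSL_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                matches = int(fields[0])
                mismatches = int(fields[1])
                q_gap_count = int(fields[4])
                q_gap_bases = int(fields[5])
                t_gap_count = int(fields[6])
                t_gap_bases = int(fields[7])
                strand = Strand(fields[8])
                q_start, q_end = int(fields[11]), int(fields[12])
                t_start, t_end = int(fields[15]), int(fields[16])
            except ValueError as exc:
                raise ValueError(f"PSL line {lineno}: {exc}") from exc
            hits.append(
                AlignmentHit(
                    query_id=fields[9],
                    target_id=fields[13],
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
            )
    return hits


def write_psl(
    hits: Iterable[AlignmentHit],
    lengths: Mapping[str, int],
    path: str | Path,
    header: bool = False,
    block_info: Mapping[int, tuple[list[int], list[int], list[int]]] | None = None,
) -> None:
    """Write hits as 21-column PSL.

    ``lengths`` must map every query and target id to its sequence length.
    Without explicit ``block_info`` (index -> blockSizes, qStarts, tStarts)
    each hit is written as a single block spanning its aligned interval.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(PSL_HEADER)
        for i, h in enumerate(hits):
            if block_info and i in block_info:
                sizes, qstarts, tstarts = block_info[i]
            else:
                sizes = [h.q_end - h.q_start]
                qstarts, tstarts = [h.q_start], [h.t_start]
            row = [
                h.matches, h.mismatches, 0, 0,
                h.q_gap_count, h.q_gap_bases, h.t_gap_count, h.t_gap_bases,
                h.strand.value,
                h.query_id, lengths[h.query_id], h.q_start, h.q_end,
                h.target_id, lengths[h.target_id], h.t_start, h.t_end,
                len(sizes),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, qstarts)) + ",",
                ",".join(map(str, tstarts)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# Tabular BLAST (-outfmt 6, 12 columns)
# ---------------------------------------------------------------------------

def parse_blast_tab(
    path: str | Path, mode: str = "nucleotide"
) -> list[AlignmentHit] | list[ProteinHit]:
    """Parse 12-column tabular BLAST output.

    ``mode='nucleotide'`` yields :class:`AlignmentHit`; ``mode='protein'``
    (BlastX-style) yields :class:`ProteinHit` with the frame derived from the
    query coordinate orientation (qstart > qend implies a negative frame) and
    rank assigned by file order within each query. BLAST's 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list = []
    ranks: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"BLAST tab line {lineno}: expected >=12 columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise ValueError(f"BLAST tab line {lineno}: {exc}") from exc
            if mode == "protein":
                reverse = qstart > qend
                lo, hi = (qend, qstart) if reverse else (qstart, qend)
                q0, q1 = lo - 1, hi
                # Orientation comes from the coordinate order; the frame index
                # is the phase of the aligned interval's forward-strand start.
                frame = -(q0 % 3 + 1) if reverse else q0 % 3 + 1
                rank = ranks.get(qid, 0) + 1
                ranks[qid] = rank
                out.append(
                    ProteinHit(
                        query_id=qid, rank=rank, frame=frame,
                        q_start=q0, q_end=q1, subject_id=sid,
                    )
                )
            else:
                lo, hi = min(qstart, qend), max(qstart, qend)
                slo, shi = min(sstart, send), max(sstart, send)
                strand = Strand.REVERSE if sstart > send or qstart > qend else Strand.FORWARD
                ident_frac = pident / 100.0
                matches = round(length * ident_frac)
                out.append(
                    AlignmentHit(
                        query_id=qid, target_id=sid, strand=strand,
                        matches=matches, mismatches=mismatch,
                        q_start=lo - 1, q_end=hi,
                        t_start=slo - 1, t_end=shi,
                        q_gap_count=gapopen, t_gap_count=0,
                        q_gap_bases=max(0, length - (hi - lo + 1)),
                        t_gap_bases=0,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Counts matrix (TSV) and sample metadata
# ---------------------------------------------------------------------------

def read_counts_tsv(
    counts_path: str | Path, meta_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a gene x sample normalized-counts TSV (header = sample ids).

    ``meta_path`` is an optional sample-metadata TSV with columns
    sample_id, strain, timepoint, replicate; without it each sample becomes
    its own strain at a single timepoint.
    """
    import pandas as pd

    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta_by_id: dict[str, SampleMeta] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype=str)
        for _, row in mdf.iterrows():
            meta_by_id[row["sample_id"]] = SampleMeta(
                sample_id=row["sample_id"],
                strain=row["strain"],
                timepoint=row["timepoint"],
                replicate=row.get("replicate", "A"),
            )
    samples = [
        meta_by_id.get(sid, SampleMeta(sample_id=sid, strain=sid, timepoint="T0"))
        for sid in df.columns
    ]
    return ExpressionMatrix(
        genes=list(df.index), samples=samples, values=df.to_numpy(dtype=float)
    )


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        matrix.values, index=matrix.genes, columns=matrix.sample_ids
    ).to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects via cyvcf2.

    Multi-allelic rows are split into one record per ALT allele; genotype
    strings are preserved per sample (``0/1`` etc., ``./.`` for no-call).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        info = {}
        for key in ("FS", "SOR", "MQ"):
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        gts = {}
        for strain, gt in zip(strains, v.genotypes):
            alleles = gt[:-1]
            sep = "|" if gt[-1] else "/"
            gts[strain] = sep.join("." if a < 0 else str(a) for a in alleles)
        for alt in v.ALT:
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    info=dict(info),
                    genotypes=dict(gts),
                )
            )
    vcf.close()
    return records


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------

class Category(str, enum.Enum):
    MERGED = "MERGED"
    ADDED_UNIQUE = "ADDED_UNIQUE"
    MANUAL = "MANUAL"


#: First comp number of each naming range.
CATEGORY_BASES: dict[Category, int] = {
    Category.MERGED: 17000000,
    Category.ADDED_UNIQUE: 17010001,
    Category.MANUAL: 17050001,
}

#: Exclusive upper bound of each range, for collision detection.
CATEGORY_LIMITS: dict[Category, int] = {
    Category.MERGED: CATEGORY_BASES[Category.ADDED_UNIQUE],
    Category.ADDED_UNIQUE: CATEGORY_BASES[Category.MANUAL],
    Category.MANUAL: 18000000,
}


class NomenclatureCounters:
    """Next-free comp number per naming category.

    The merged, added-unique and manual ranges are disjoint by construction;
    exhausting a range raises rather than silently colliding with the next.
    """

    def __init__(self) -> None:
        self._next = dict(CATEGORY_BASES)

    def allocate_locus(self, category: Category) -> str:
        n = self._next[category]
        if n >= CATEGORY_LIMITS[category]:
            raise ValueError(
                f"nomenclature range exhausted for {category.value}: "
                f"comp number {n} would collide with the next category"
            )
        self._next[category] = n + 1
        return f"comp{n}_c0"


def assign_nomenclature(
    records: Sequence[Sequence[TranscriptRecord]] | Sequence[TranscriptRecord],
    category: Category,
    counters: NomenclatureCounters,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Rename records into the Trinity-style namespace of ``category``.

    ``records`` is a list of loci, each a list of isoform records (a flat
    list of records is treated as one-singleton-locus-per-record). Each locus
    receives ``comp<N>_c0`` with isoforms ``_seq1, _seq2, ...`` in input
    order. Returns the renamed records and the old->new id mapping.
    """
    loci: list[list[TranscriptRecord]]
    if records and isinstance(records[0], TranscriptRecord):
        loci = [[r] for r in records]  # type: ignore[list-item]
    else:
        loci = [list(l) for l in records]  # type: ignore[union-attr]

    renamed: list[TranscriptRecord] = []
    mapping: dict[str, str] = {}
    for locus in loci:
        locus_id = counters.allocate_locus(category)
        for i, rec in enumerate(locus, start=1):
            new_id = f"{locus_id}_seq{i}"
            mapping[rec.id] = new_id
            renamed.append(replace(rec, id=new_id, locus_id=locus_id))
    return renamed, mapping


def locus_of(transcript_id: str) -> str | None:
    """Extract the ``comp<N>_c<M>`` locus prefix from a Trinity-style id."""
    m = _TRINITY_ID_RE.match(transcript_id)
    if m is None:
        return None
    return f"comp{m.group(1)}_c{m.group(2)}"
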