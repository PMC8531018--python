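"""Seeded fixture generators with planted, machine-readable ground truth.

Every input the pipeline consumes can be generated here offline: paired
assemblies with planted unique/redundant/bridge transcripts, transcripts
with planted ORFs and fused chimeras, boundary-straddling VCFs, taxon hit
tables with planted contaminants, and expression matrices with planted
per-strain expression patterns. Generators are deterministic under their
seed (regenerating writes byte-identical files).

Sequence composition defaults to 68% GC, matching the organism's
GC-rich genome. Alignments in the unify fixture are produced by the
package's naive exact-k-mer aligner, so no external aligner is needed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .decontam import HitKind, TaxHit
from .io_model import (
    AlignmentHit,
    ExpressionMatrix,
    ProteinHit,
    SampleMeta,
    Source,
    TranscriptRecord,
    write_counts_tsv,
    write_fasta,
    write_psl,
)
from .naive_align import align_all
from .orf_translate import STOP_CODONS, _CODON_TABLE

DEFAULT_GC = 0.68

_NONSTOP_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*" and c != "ATG")


def random_seq(rng: random.Random, length: int, gc: float = DEFAULT_GC) -> str:
    half_gc, half_at = gc / 2, (1 - gc) / 2
    bases = "GCAT"
    weights = [half_gc, half_gc, half_at, half_at]
    return "".join(rng.choices(bases, weights=weights, k=length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in "ACGT" if x != b])
    return "".join(out)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# Unify scenario
# ---------------------------------------------------------------------------

@dataclass
class UnifyFixture:
    base: list[TranscriptRecord]
    query: list[TranscriptRecord]
    hits: list[AlignmentHit]
    truth: dict[str, str]  # query id -> planted category
    bridge_truth: dict[str, tuple[str, str, str]]  # bridge id -> (a5, a3, gene seq)


def gen_unify_fixture(
    seed: int,
    n_base: int = 50,
    n_unique: int = 3,
    n_redundant: int = 2,
    n_bridges: int = 1,
    mutation_rate: float = 0.005,
    gc: float = DEFAULT_GC,
    k: int = 20,
    out_dir: str | Path | None = None,
) -> UnifyFixture:
    """Two assemblies with planted unique, redundant, and bridge queries.

    Each bridge scenario plants a full-length gene G split into a 5' and a
    3' fragment in the base assembly, with a query transcript spanning the
    missing middle; merging must reconstruct G exactly. Unique queries share
    no k-mer with the base assembly; redundant queries are (lightly mutated)
    substrings of base transcripts. The PSL-style hits come from the naive
    exact-k-mer aligner.
    """
    if not 0 <= mutation_rate <= 0.02:
        raise ValueError("mutation_rate must be in [0, 0.02]")
    if n_base < 2 * n_bridges + max(1, n_redundant):
        raise ValueError("n_base too small for the requested planted categories")

    rng = random.Random(seed)
    base: list[TranscriptRecord] = []
    query: list[TranscriptRecord] = []
    truth: dict[str, str] = {}
    bridge_truth: dict[str, tuple[str, str, str]] = {}

    # plain base transcripts
    n_plain = n_base - 2 * n_bridges
    for i in range(n_plain):
        base.append(
            TranscriptRecord(
                id=f"base{i + 1:04d}",
                seq=random_seq(rng, rng.randint(500, 3000), gc),
                source=Source.BASE,
            )
        )

    # bridge scenarios: gene G = [anchor5 | gap | anchor3], bridge spans the gap
    for b in range(n_bridges):
        gene = random_seq(rng, 3000, gc)
        a5_end, gap_end = 1400, 1600
        br_lo, br_hi = 1200, 1900
        if br_lo + k > a5_end or gap_end + k > br_hi:
            raise ValueError("bridge overlap windows shorter than the seed k-mer")
        a5 = TranscriptRecord(f"anchor5_{b + 1:02d}", gene[:a5_end], Source.BASE)
        a3 = TranscriptRecord(f"anchor3_{b + 1:02d}", gene[gap_end:], Source.BASE)
        bridge = TranscriptRecord(f"bridge{b + 1:02d}", gene[br_lo:br_hi], Source.QUERY)
        base.extend([a5, a3])
        query.append(bridge)
        truth[bridge.id] = "MERGE"
        bridge_truth[bridge.id] = (a5.id, a3.id, gene)

    # redundant queries: mutated substrings of plain base transcripts
    for r in range(n_redundant):
        src = base[r % n_plain]
        span = rng.randint(300, max(301, len(src) - 1))
        start = rng.randint(0, len(src) - span)
        seq = _mutate(rng, src.seq[start : start + span], mutation_rate)
        rec = TranscriptRecord(f"redundant{r + 1:02d}", seq, Source.QUERY)
        query.append(rec)
        truth[rec.id] = "REDUNDANT"

    # unique queries: share no k-mer with the base assembly
    base_kmers: set[str] = set()
    for rec in base:
        base_kmers |= _kmers(rec.seq, k)
    for u in range(n_unique):
        for _ in range(1000):
            seq = random_seq(rng, rng.randint(400, 1500), gc)
            if not (_kmers(seq, k) & base_kmers):
                break
        else:
            raise RuntimeError("could not sample a unique query; base k-mer space saturated")
        rec = TranscriptRecord(f"unique{u + 1:02d}", seq, Source.QUERY)
        query.append(rec)
        truth[rec.id] = "UNIQUE"

    rng.shuffle(query)
    hits = align_all(
        [(q.id, q.seq) for q in query], [(t.id, t.seq) for t in base], k=k,
        skip_self=False,
    )

    fx = UnifyFixture(base=base, query=query, hits=hits, truth=truth,
                      bridge_truth=bridge_truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(base, out / "base.fa")
        write_fasta(query, out / "query.fa")
        lengths = {r.id: len(r) for r in base + query}
        write_psl(hits, lengths, out / "q_vs_b.psl")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("query_id\tcategory\tanchor5\tanchor3\n")
            for q in query:
                a5, a3, _ = bridge_truth.get(q.id, ("", "", ""))
                fh.write(f"{q.id}\t{truth[q.id]}\t{a5}\t{a3}\n")
        write_fasta(
            [
                TranscriptRecord(f"{bid}_gene", gene, Source.MERGED)
                for bid, (_, _, gene) in sorted(bridge_truth.items())
            ],
            out / "truth_merged.fa",
        )
    return fx


# ---------------------------------------------------------------------------
# ORF / chimera scenario
# ---------------------------------------------------------------------------

@dataclass
class PlantedOrf:
    frame: int
    nt_start: int
    nt_end: int  # includes the terminal stop codon
    protein: str


@dataclass
class OrfFixture:
    records: list[TranscriptRecord]
    hits_by_query: dict[str, list[ProteinHit]]
    truth_orfs: dict[str, PlantedOrf]  # coding records
    noncoding_ids: list[str]
    chimera_truth: dict[str, int]  # chimera id -> expected number of parts


def _orf_cassette(
    rng: random.Random, protein_len: int, flank5: int, flank3: int, gc: float
) -> tuple[str, int, int, str]:
    """Forward-strand cassette: flank + in-frame stop + ATG...stop + flank.

    Returns (sequence, orf_start, orf_end, protein); coordinates are on the
    built (working) strand and include the terminal stop.
    """
    # pad the 5' flank so the planted stop sits in frame +1 of the cassette
    f5 = random_seq(rng, flank5 + (-flank5) % 3, gc)
    codons = [rng.choice(_NONSTOP_CODONS) for _ in range(protein_len - 1)]
    orf_nt = "ATG" + "".join(codons) + rng.choice(sorted(STOP_CODONS))
    protein = "M" + "".join(_CODON_TABLE[c] for c in codons)
    pre = f5 + rng.choice(sorted(STOP_CODONS))
    seq = pre + orf_nt + random_seq(rng, flank3, gc)
    return seq, len(pre), len(pre) + len(orf_nt), protein


def _plant_coding(
    rng: random.Random,
    rec_id: str,
    frame: int,
    protein_len: int,
    gc: float,
    flank5: int = 120,
    flank3: int = 120,
) -> tuple[TranscriptRecord, PlantedOrf]:
    working, w_start, w_end, protein = _orf_cassette(rng, protein_len, flank5, flank3, gc)
    # shift the cassette into the requested frame by prepending bases
    offset = abs(frame) - 1
    working = random_seq(rng, offset, gc) + working
    w_start, w_end = w_start + offset, w_end + offset
    if frame > 0:
        seq = working
        nt_start, nt_end = w_start, w_end
    else:
        from .naive_align import revcomp

        seq = revcomp(working)
        nt_start, nt_end = len(working) - w_end, len(working) - w_start
    return (
        TranscriptRecord(rec_id, seq, Source.BASE),
        PlantedOrf(frame, nt_start, nt_end, protein),
    )


def gen_orf_fixture(
    seed: int,
    n_coding: int = 10,
    n_noncoding: int = 5,
    n_chimera: int = 3,
    gc: float = DEFAULT_GC,
    max_reject_iter: int = 20000,
    out_dir: str | Path | None = None,
) -> OrfFixture:
    """Transcripts with planted ORFs, non-coding records, and fused chimeras.

    Coding records carry a planted ORF of 60-220 aa in a known frame with an
    immediately upstream in-frame stop, plus three synthetic protein hits in
    the true frame. Non-coding records are rejection-sampled so that no
    frame yields a 50-aa protein. Chimeras fuse two coding cassettes whose
    ORFs each exceed 300 aa, with total length above 2000 bp.
    """
    from .orf_translate import find_orfs_six_frame

    rng = random.Random(seed)
    frames = (1, 2, 3, -1, -2, -3)
    records: list[TranscriptRecord] = []
    hits_by_query: dict[str, list[ProteinHit]] = {}
    truth_orfs: dict[str, PlantedOrf] = {}
    noncoding_ids: list[str] = []
    chimera_truth: dict[str, int] = {}

    for i in range(n_coding):
        frame = frames[i % len(frames)]
        rec, planted = _plant_coding(
            rng, f"coding{i + 1:03d}", frame, rng.randint(60, 220), gc
        )
        records.append(rec)
        truth_orfs[rec.id] = planted
        # three agreeing hits covering sub-intervals of the planted ORF
        span = planted.nt_end - planted.nt_start
        hits = []
        for rank in range(1, 4):
            lo = planted.nt_start + rng.randrange(0, max(1, span // 4))
            hi = planted.nt_end - 3 - rng.randrange(0, max(1, span // 4))
            hits.append(
                ProteinHit(
                    query_id=rec.id, rank=rank, frame=frame,
                    q_start=lo, q_end=max(lo + 3, hi),
                    subject_id=f"sp|SYN{seed}{i:03d}{rank}",
                )
            )
        hits_by_query[rec.id] = hits

    for i in range(n_noncoding):
        for _ in range(max_reject_iter):
            seq = random_seq(rng, 240, gc)
            longest = max(
                (len(o.protein) for o in find_orfs_six_frame(seq)), default=0
            )
            if longest < 50:
                break
        else:
            raise RuntimeError(
                "rejection sampling failed; try shorter non-coding records"
            )
        rec = TranscriptRecord(f"noncoding{i + 1:03d}", seq, Source.BASE)
        records.append(rec)
        noncoding_ids.append(rec.id)

    for i in range(n_chimera):
        part_a, _ = _plant_coding(
            rng, "tmpA", 1, rng.randint(310, 360), gc, flank5=60, flank3=60
        )
        part_b, _ = _plant_coding(
            rng, "tmpB", 1, rng.randint(310, 360), gc, flank5=60, flank3=60
        )
        rec = TranscriptRecord(
            f"chimera{i + 1:03d}", part_a.seq + part_b.seq, Source.BASE
        )
        if len(rec) <= 2000:
            raise RuntimeError("planted chimera unexpectedly short")
        records.append(rec)
        chimera_truth[rec.id] = 2

    fx = OrfFixture(
        records=records, hits_by_query=hits_by_query, truth_orfs=truth_orfs,
        noncoding_ids=noncoding_ids, chimera_truth=chimera_truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "transcripts.fa")
        with open(out / "protein_hits.tsv", "w") as fh:
            for rec_id in sorted(hits_by_query):
                for h in hits_by_query[rec_id]:
                    # 12-column tabular BLAST, 1-based inclusive coordinates
                    qs, qe = (h.q_start + 1, h.q_end) if h.frame > 0 else (h.q_end, h.q_start + 1)
                    fh.write(
                        "\t".join(
                            map(str, [h.query_id, h.subject_id, 90.0,
                                      (h.q_end - h.q_start) // 3, 0, 0, qs, qe,
                                      1, (h.q_end - h.q_start) // 3, 1e-30, 200.0])
                        )
                        + "\n"
                    )
        with open(out / "truth.tsv", "w") as fh:
            fh.write("id\tkind\tframe\tnt_start\tnt_end\n")
            for rid, p in truth_orfs.items():
                fh.write(f"{rid}\tcoding\t{p.frame}\t{p.nt_start}\t{p.nt_end}\n")
            for rid in noncoding_ids:
                fh.write(f"{rid}\tnoncoding\t\t\t\n")
            for rid, n in chimera_truth.items():
                fh.write(f"{rid}\tchimera_{n}_parts\t\t\t\n")
    return fx


# ---------------------------------------------------------------------------
# Variant scenario
# ---------------------------------------------------------------------------

DEFAULT_STRAINS = ("CCMP2090", "CCMP373", "CCMP374", "CCMP379")


@dataclass
class VariantFixture:
    vcf_path: Path | None
    rows: list[dict]
    truth_pass: list[bool]
    truth_strain_sets: dict[str, set[tuple[str, int]]]
    strains: tuple[str, ...]


def _passes_truth(row: dict) -> bool:
    """Ground-truth clause evaluation, written out longhand at generation."""
    is_indel = len(row["ref"]) != len(row["alt"])
    if is_indel:
        if row["qual"] < 40.0:
            return False
        if row["info"].get("FS", float("-inf")) > 200.0:
            return False
        if abs(len(row["ref"]) - len(row["alt"])) >= 15:
            return False
        return True
    if row["qual"] < 40.0:
        return False
    if row["info"].get("FS", float("-inf")) > 60.0:
        return False
    if row["info"].get("SOR", float("-inf")) > 3.0:
        return False
    if row["info"].get("MQ", float("inf")) < 40.0:
        return False
    return True


def gen_variant_fixture(
    seed: int,
    n_strains: int = 4,
    n_records: int = 40,
    out_dir: str | Path | None = None,
) -> VariantFixture:
    """A VCF whose records straddle every hard-filter boundary.

    The first block of records systematically hits both sides of each
    threshold (QUAL 39.9/40.0, FS 60.0/60.1 for SNPs and 200.0/200.1 for
    indels, SOR 3.0/3.1, MQ 39.9/40.0, indel length differences 14/15/16);
    the rest are random. Genotypes per strain are drawn from a seeded
    distribution; the truth pass/fail vector and per-strain SNP position
    sets are derived by direct clause evaluation at generation time.
    """
    if n_strains < 1:
        raise ValueError("need at least one strain")
    rng = random.Random(seed)
    strains = tuple(
        DEFAULT_STRAINS[i] if i < len(DEFAULT_STRAINS) else f"STRAIN{i + 1}"
        for i in range(n_strains)
    )
    chroms = [f"comp{17000000 + i}_c0_seq1" for i in range(5)]

    boundary = [
        # SNPs around each threshold; unlisted annotations stay at safe values
        dict(qual=39.9, FS=1.0, SOR=1.0, MQ=60.0, indel=0),
        dict(qual=40.0, FS=1.0, SOR=1.0, MQ=60.0, indel=0),
        dict(qual=50.0, FS=60.0, SOR=1.0, MQ=60.0, indel=0),
        dict(qual=50.0, FS=60.1, SOR=1.0, MQ=60.0, indel=0),
        dict(qual=50.0, FS=1.0, SOR=3.0, MQ=60.0, indel=0),
        dict(qual=50.0, FS=1.0, SOR=3.1, MQ=60.0, indel=0),
        dict(qual=50.0, FS=1.0, SOR=1.0, MQ=39.9, indel=0),
        dict(qual=50.0, FS=1.0, SOR=1.0, MQ=40.0, indel=0),
        # indels around QUAL/FS/length
        dict(qual=39.9, FS=1.0, indel=2),
        dict(qual=40.0, FS=200.0, indel=2),
        dict(qual=50.0, FS=200.1, indel=2),
        dict(qual=50.0, FS=1.0, indel=14),
        dict(qual=50.0, FS=1.0, indel=15),
        dict(qual=50.0, FS=1.0, indel=16),
    ]

    rows: list[dict] = []
    pos_by_chrom = {c: 0 for c in chroms}
    gt_choices = ["0/0", "0/1", "1/1", "./."]
    gt_weights = [0.55, 0.2, 0.15, 0.1]

    def _make_row(spec: dict) -> dict:
        chrom = rng.choice(chroms)
        pos_by_chrom[chrom] += rng.randint(5, 50)
        pos = pos_by_chrom[chrom]
        ref_base = rng.choice("ACGT")
        if spec["indel"]:
            ref = ref_base
            alt = ref_base + random_seq(rng, spec["indel"], 0.5)
        else:
            ref = ref_base
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
        info = {k: spec[k] for k in ("FS", "SOR", "MQ") if k in spec}
        gts = {s: rng.choices(gt_choices, weights=gt_weights)[0] for s in strains}
        return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=spec["qual"],
                    info=info, genotypes=gts)

    for spec in boundary:
        rows.append(_make_row(spec))
    for _ in range(max(0, n_records - len(boundary))):
        if rng.random() < 0.7:
            spec = dict(
                qual=round(rng.uniform(20, 80), 1),
                FS=round(rng.uniform(0, 120), 1),
                SOR=round(rng.uniform(0, 5), 2),
                MQ=round(rng.uniform(20, 60), 1),
                indel=0,
            )
        else:
            spec = dict(
                qual=round(rng.uniform(20, 80), 1),
                FS=round(rng.uniform(0, 300), 1),
                indel=rng.randint(1, 20),
            )
        rows.append(_make_row(spec))

    rows.sort(key=lambda r: (r["chrom"], r["pos"]))
    truth_pass = [_passes_truth(r) for r in rows]
    truth_sets: dict[str, set[tuple[str, int]]] = {s: set() for s in strains}
    for row, ok in zip(rows, truth_pass):
        if not ok or len(row["ref"]) != len(row["alt"]):
            continue
        for s in strains:
            gt = row["genotypes"][s]
            if gt not in ("0/0", "./."):
                truth_sets[s].add((row["chrom"], row["pos"]))

    vcf_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf_path = out / "variants.vcf"
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c},length=100000>\n")
            for k, d in (
                ("FS", "Phred-scaled Fisher strand bias"),
                ("SOR", "Symmetric odds ratio strand bias"),
                ("MQ", "RMS mapping quality"),
            ):
                fh.write(
                    f'##INFO=<ID={k},Number=1,Type=Float,Description="{d}">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(strains) + "\n"
            )
            for row in rows:
                info = ";".join(f"{k}={v}" for k, v in sorted(row["info"].items()))
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                    f"{row['qual']}\t.\t{info or '.'}\tGT\t"
                    + "\t".join(row["genotypes"][s] for s in strains) + "\n"
                )
    return VariantFixture(
        vcf_path=vcf_path, rows=rows, truth_pass=truth_pass,
        truth_strain_sets=truth_sets, strains=strains,
    )


# ---------------------------------------------------------------------------
# Decontamination scenario
# ---------------------------------------------------------------------------

@dataclass
class DecontamFixture:
    records: list[TranscriptRecord]
    hits_by_query: dict[str, list[TaxHit]]
    locus_of_rep: dict[str, str]
    locus_members: dict[str, list[str]]
    contaminant_loci: set[str]


def gen_decontam_fixture(
    seed: int,
    n_loci: int = 50,
    n_contam: int = 5,
    gc: float = DEFAULT_GC,
) -> DecontamFixture:
    """Loci with isoforms, of which ``n_contam`` are planted contaminants.

    Contaminants rotate through the three removal routes: near-identical
    foreign protein hit, near-identical long foreign nucleotide hit, and
    short transcripts with no trusted hit at all. Clean loci have a trusted
    best hit (or are long enough to survive hitlessness).
    """
    rng = random.Random(seed)
    records: list[TranscriptRecord] = []
    hits_by_query: dict[str, list[TaxHit]] = {}
    locus_of_rep: dict[str, str] = {}
    locus_members: dict[str, list[str]] = {}
    contaminant_loci: set[str] = set()
    contam_indices = set(rng.sample(range(n_loci), n_contam))

    foreign_taxa = ["Escherichia coli", "Vibrio parahaemolyticus", "Homo sapiens"]
    trusted_taxa = ["Emiliania huxleyi CCMP1516", "Chrysochromulina tobinii",
                    "Guillardia theta CCMP2712"]

    for i in range(n_loci):
        locus_id = f"comp{17010001 + i}_c0"
        n_iso = rng.randint(1, 4)
        contaminant = i in contam_indices
        route = i % 3
        members = []
        for j in range(1, n_iso + 1):
            length = (
                rng.randint(200, 340)
                if contaminant and route == 2 and j == 1
                else rng.randint(400, 1500)
            )
            rec = TranscriptRecord(
                f"{locus_id}_seq{j}", random_seq(rng, length, gc), Source.BASE,
                locus_id=locus_id,
            )
            records.append(rec)
            members.append(rec.id)
        rep = members[0]
        locus_of_rep[rep] = locus_id
        locus_members[locus_id] = members
        if contaminant:
            contaminant_loci.add(locus_id)
            if route == 0:
                hits_by_query[rep] = [
                    TaxHit(rep, rng.choice(foreign_taxa), HitKind.PROTEIN,
                           round(rng.uniform(0.95, 0.99), 3), 0.8, rank=1)
                ]
            elif route == 1:
                hits_by_query[rep] = [
                    TaxHit(rep, rng.choice(foreign_taxa), HitKind.NUCLEOTIDE,
                           round(rng.uniform(0.95, 0.99), 3),
                           round(rng.uniform(0.5, 0.9), 2), rank=1)
                ]
            else:
                hits_by_query[rep] = []  # short orphan: no hits at all
        else:
            hits_by_query[rep] = [
                TaxHit(rep, rng.choice(trusted_taxa), HitKind.PROTEIN,
                       round(rng.uniform(0.5, 0.99), 3), 0.7, rank=1)
            ]
    return DecontamFixture(
        records=records, hits_by_query=hits_by_query, locus_of_rep=locus_of_rep,
        locus_members=locus_members, contaminant_loci=contaminant_loci,
    )


# ---------------------------------------------------------------------------
# Expression scenario
# ---------------------------------------------------------------------------

@dataclass
class ExpressionFixture:
    matrix: ExpressionMatrix
    truth_expressed: set[str]
    truth_unique_sets: dict[str, set[str]]


def gen_expression_fixture(
    seed: int,
    n_genes: int = 200,
    out_dir: str | Path | None = None,
) -> ExpressionFixture:
    """Counts matrix with planted expressed genes and per-strain patterns.

    The sample layout mirrors the two-experiment design: two strains with
    day-2/day-12 replicate pairs and one strain with a single non-infected
    day-1 sample. Per-strain exponential-growth expression membership is
    planted per gene, as is overall expressed status (>= 7 reads in >= 3
    samples).
    """
    import numpy as np

    rng = random.Random(seed)
    samples = [
        SampleMeta("s373_T2_A", "CCMP373", "T2", "A"),
        SampleMeta("s373_T2_B", "CCMP373", "T2", "B"),
        SampleMeta("s373_T12_A", "CCMP373", "T12", "A"),
        SampleMeta("s373_T12_B", "CCMP373", "T12", "B"),
        SampleMeta("s374_T2_A", "CCMP374", "T2", "A"),
        SampleMeta("s374_T2_B", "CCMP374", "T2", "B"),
        SampleMeta("s374_T12_A", "CCMP374", "T12", "A"),
        SampleMeta("s374_T12_B", "CCMP374", "T12", "B"),
        SampleMeta("s2090_T1", "CCMP2090", "T1", "A"),
    ]
    strains = ("CCMP2090", "CCMP373", "CCMP374")
    exp_cols = {
        "CCMP373": [0, 1],
        "CCMP374": [4, 5],
        "CCMP2090": [8],
    }
    genes = [f"comp{17010001 + i}_c0" for i in range(n_genes)]
    values = np.zeros((n_genes, len(samples)))
    truth_unique: dict[str, set[str]] = {s: set() for s in strains}
    truth_expressed: set[str] = set()

    for gi, gene in enumerate(genes):
        # low background everywhere
        for si in range(len(samples)):
            values[gi, si] = round(rng.uniform(0, 6.9), 2)
        member_strains = [s for s in strains if rng.random() < 0.45]
        for s in member_strains:
            truth_unique[s].add(gene)
            for col in exp_cols[s]:
                values[gi, col] = round(rng.uniform(7, 500), 2)
        # ensure at most 2 background samples sneak over threshold: background
        # is capped at 6.9, so expressed status is driven by planted columns
        n_high = int((values[gi] >= 7).sum())
        if rng.random() < 0.5 and n_high < 3:
            # plant extra high samples in stationary phase to cross 3 samples
            extra = rng.sample([2, 3, 6, 7], 3 - n_high)
            for col in extra:
                values[gi, col] = round(rng.uniform(7, 500), 2)
        if int((values[gi] >= 7).sum()) >= 3:
            truth_expressed.add(gene)

    matrix = ExpressionMatrix(genes=genes, samples=samples, values=values)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(matrix, out / "counts.tsv")
        with open(out / "meta.tsv", "w") as fh:
            fh.write("sample_id\tstrain\ttimepoint\treplicate\n")
            for s in samples:
                fh.write(f"{s.sample_id}\t{s.strain}\t{s.timepoint}\t{s.replicate}\n")
    return ExpressionFixture(
        matrix=matrix, truth_expressed=truth_expressed, truth_unique_sets=truth_unique
    )
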