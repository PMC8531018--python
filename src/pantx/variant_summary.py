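"""Hard filtering of called variants and per-strain variation summaries.

SNPs fail on QUAL < 40, FS > 60, SOR > 3 or MQ < 40; indels fail on
QUAL < 40 or FS > 200, and indels with a length difference of 15 bp or more
are removed outright (long apparent indels in transcript space are usually
retained introns, not real variation). A missing annotation can never fail a
record, matching GATK hard-filter behavior for absent annotations.

A strain carries a SNP at a position when its genotype there differs from
the reference, whether homo- or heterozygous; no-calls (./.) never count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_model import VariantRecord


@dataclass
class SnpFilterThresholds:
    qual_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mq_min: float = 40.0


@dataclass
class IndelFilterThresholds:
    qual_min: float = 40.0
    fs_max: float = 200.0


@dataclass
class VariantFilterParams:
    snp: SnpFilterThresholds = field(default_factory=SnpFilterThresholds)
    indel: IndelFilterThresholds = field(default_factory=IndelFilterThresholds)
    #: records with |len(ref) - len(alt)| >= this are removed ("shorter than
    #: 15 bp were kept"); override to 16 for the inclusive reading.
    indel_max_len: int = 15


def failed_clauses(rec: VariantRecord, params: VariantFilterParams | None = None) -> list[str]:
    """Names of the filter clauses a record fails (empty = PASS)."""
    params = params or VariantFilterParams()
    info = rec.info
    fails: list[str] = []
    if rec.is_indel:
        if rec.qual < params.indel.qual_min:
            fails.append("QUAL")
        if info.get("FS") is not None and info["FS"] > params.indel.fs_max:
            fails.append("FS")
        if rec.indel_length >= params.indel_max_len:
            fails.append("INDEL_LEN")
    else:
        if rec.qual < params.snp.qual_min:
            fails.append("QUAL")
        if info.get("FS") is not None and info["FS"] > params.snp.fs_max:
            fails.append("FS")
        if info.get("SOR") is not None and info["SOR"] > params.snp.sor_max:
            fails.append("SOR")
        if info.get("MQ") is not None and info["MQ"] < params.snp.mq_min:
            fails.append("MQ")
    return fails


def hard_filter(
    records: Sequence[VariantRecord],
    params: VariantFilterParams | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition records into passing ones and a fail log.

    The fail log records every clause that fired for each failing record.
    Filtering is per-record, hence deterministic and order-independent.
    """
    params = params or VariantFilterParams()
    passing: list[VariantRecord] = []
    failed: list[tuple[VariantRecord, list[str]]] = []
    for rec in records:
        clauses = failed_clauses(rec, params)
        if clauses:
            failed.append((rec, clauses))
        else:
            passing.append(rec)
    return passing, failed


def filter_vcf_file(
    vcf_in: str | Path,
    vcf_out: str | Path,
    params: VariantFilterParams | None = None,
) -> dict[str, int]:
    """Annotate a VCF's FILTER column with PASS or the failed clause names.

    Returns pass/fail counts. Multi-allelic rows fail if any ALT fails.
    """
    from cyvcf2 import VCF, Writer

    params = params or VariantFilterParams()
    vcf = VCF(str(vcf_in))
    for name, desc in (
        ("QUAL", "Low variant quality"),
        ("FS", "Fisher strand bias"),
        ("SOR", "Symmetric odds ratio strand bias"),
        ("MQ", "Low mapping quality"),
        ("INDEL_LEN", "Indel length at or above the retention cutoff"),
    ):
        vcf.add_filter_to_header({"ID": name, "Description": desc})
    writer = Writer(str(vcf_out), vcf)
    counts = {"pass": 0, "fail": 0}
    for v in vcf:
        info = {
            k: float(v.INFO.get(k)) for k in ("FS", "SOR", "MQ") if v.INFO.get(k) is not None
        }
        clauses: list[str] = []
        for alt in v.ALT:
            rec = VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                qual=float(v.QUAL) if v.QUAL is not None else 0.0, info=info,
            )
            for c in failed_clauses(rec, params):
                if c not in clauses:
                    clauses.append(c)
        v.FILTER = ";".join(clauses) if clauses else "PASS"
        counts["fail" if clauses else "pass"] += 1
        writer.write_record(v)
    writer.close()
    vcf.close()
    return counts


# ---------------------------------------------------------------------------
# Per-strain SNP sets and summaries
# ---------------------------------------------------------------------------

_NON_VARIANT_GENOTYPES = {"0/0", "0|0", "./.", ".|.", "."}


def _carries_variant(genotype: str) -> bool:
    alleles = genotype.replace("|", "/").split("/")
    return any(a not in (".", "0") for a in alleles)


def call_strain_snps(
    records: Sequence[VariantRecord],
    strains: Sequence[str] | None = None,
) -> dict[str, set[tuple[str, int]]]:
    """Per-strain sets of (chrom, pos) at which the strain differs from the
    reference, homo- or heterozygous; ./. is a no-call and never counts."""
    if strains is None:
        strains = sorted({s for r in records for s in r.genotypes})
    sets: dict[str, set[tuple[str, int]]] = {s: set() for s in strains}
    for rec in records:
        for strain in strains:
            if strain not in rec.genotypes:
                raise ValueError(f"strain {strain!r} absent from record genotypes")
            if _carries_variant(rec.genotypes[strain]):
                sets[strain].add((rec.chrom, rec.pos))
    return sets


def intersections(per_strain: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact-membership intersection counts over every non-empty strain
    subset (the numbers an UpSet plot displays).

    Each element of the union is counted once, in the subset of strains that
    contain it, so the counts partition the union.
    """
    strains = sorted(per_strain)
    if not strains:
        raise ValueError("need at least one strain")
    union = set().union(*per_strain.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(strains) + 1):
        for combo in combinations(strains, r):
            counts[frozenset(combo)] = 0
    for item in union:
        members = frozenset(s for s in strains if item in per_strain[s])
        counts[members] += 1
    total = sum(counts.values())
    assert total == len(union), "intersection counts must partition the union"
    return counts


@dataclass
class StrainVariantProfile:
    strain: str
    n_snp_positions: int
    mapped_bases: int
    snps_per_mapped_base: float
    snps_per_gene_mean: float
    genes_counted: int
    covered_only: bool


def per_gene_stats(
    per_strain: Mapping[str, set[tuple[str, int]]],
    gene_ids: Sequence[str],
    mapped_bases: Mapping[str, int],
    covered_genes: Mapping[str, Iterable[str]] | None = None,
) -> list[StrainVariantProfile]:
    """Mean SNPs per gene and SNPs per mapped base for each strain.

    With ``covered_genes`` (per-strain iterables of genes with >= 1 mapped
    read) the per-gene mean averages over covered genes only; otherwise over
    all genes. The choice is recorded on each profile.
    """
    profiles = []
    for strain in sorted(per_strain):
        positions = per_strain[strain]
        mb = mapped_bases.get(strain, 0)
        if mb <= 0:
            raise ValueError(f"strain {strain!r} has zero mapped bases")
        per_gene: dict[str, int] = {}
        for chrom, _pos in positions:
            per_gene[chrom] = per_gene.get(chrom, 0) + 1
        if covered_genes is not None:
            denom_genes = list(covered_genes[strain])
        else:
            denom_genes = list(gene_ids)
        if not denom_genes:
            raise ValueError(f"strain {strain!r} has no genes to average over")
        mean = sum(per_gene.get(g, 0) for g in denom_genes) / len(denom_genes)
        profiles.append(
            StrainVariantProfile(
                strain=strain,
                n_snp_positions=len(positions),
                mapped_bases=mb,
                snps_per_mapped_base=len(positions) / mb,
                snps_per_gene_mean=mean,
                genes_counted=len(denom_genes),
                covered_only=covered_genes is not None,
            )
        )
    return profiles


def write_intersections_tsv(counts: Mapping[frozenset, int], path: str | Path) -> None:
    """TSV of subset -> exact-membership count, consumable by UpSet tools."""
    with open(path, "w") as fh:
        fh.write("strains\tcount\n")
        for combo in sorted(counts, key=lambda c: (len(c), sorted(c))):
            fh.write("&".join(sorted(combo)) + f"\t{counts[combo]}\n")
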