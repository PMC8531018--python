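# pantx

Tools for building and exploiting a **pan-transcriptome**: a single
non-redundant reference transcript set unified across strains of one
species, here modeled on multi-strain work in the coccolithophore
*Emiliania huxleyi*. When no reference genome is adequate, each strain gets
a de novo transcriptome assembly; `pantx` merges two such assemblies into
one locus/isoform catalogue and provides the downstream conventions that a
common reference enables — contamination screening, homology-guided
translation, multi-strain variant summaries, and expression set operations.

## What it does

**Unification** (`pantx unify`). Every transcript of a *query* assembly is
classified against a *base* assembly from Blat-style alignments:

* no alignment with score ≥ 100 (score = matches − mismatches −
  query-gap count − target-gap count) → **added** as unique;
* alignments to two distinct base transcripts, one covering the query's 5′
  side near that anchor's 3′ end and one the 3′ side near the other
  anchor's 5′ end, with per-alignment internal gaps ≤ 200 bp and outer
  overhangs ≤ 100 bp → the three fragments are **merged** into one longer
  transcript (base sequence kept verbatim where they overlap);
* anything else → **redundant**, dropped in favor of the base transcript.

Added transcripts are clustered into loci by single linkage over pairwise
identity (≥ 95% identity covering ≥ 20% of both members), and all new
records get Trinity-style names: merged loci from `comp17000000_c0_seq1`,
added loci from `comp17010001_c0_seq1`, manually curated genes from
`comp17050001_c0_seq1` (a manual gene displaces any automatic transcript it
hits with score ≥ 200).

**Decontamination** (`pantx decontam`). A locus representative is kept if
its best homology hit is the organism itself or a short list of trusted
relatives; it is removed on a ≥ 95% foreign protein similarity, on a ≥ 95%
foreign nucleotide identity covering ≥ 50% of the transcript, or when it is
under 350 bp with no trusted hit at all. Removal cascades to all isoforms
of the locus.

**Translation** (`pantx translate`). Six-frame ORF enumeration; the frame
is chosen by majority among the top three protein (BlastX-style) hits, with
fallbacks to the longest hit-overlapping ORF and then to the longest ORF
overall. A methionine start is required only downstream of an in-frame
stop. Proteins under 50 aa mark non-coding candidates (plastid transcripts
exempt). Transcripts over 2000 bp whose longest ORF covers < 80% of their
length are screened as chimeras and split between non-overlapping ORFs of
≥ 300 aa each (up to 3 parts).

**Variants** (`pantx variants`). GATK-style hard filters — SNPs fail on
QUAL < 40, FS > 60, SOR > 3 or MQ < 40; indels on QUAL < 40 or FS > 200,
with length differences ≥ 15 bp removed as likely intron retention. A
strain carries a SNP wherever its genotype differs from the reference,
homo- or heterozygous; per-strain sets feed UpSet-style intersection counts
and per-gene / per-mapped-base rates.

**Expression** (`pantx express`). Expressed genes need ≥ 7 normalized reads
in ≥ 3 samples; per-strain "digital Venn" partitions use ≥ 7 reads in *all*
of a strain's exponential-growth samples; gene-wise z-scores feed seeded
k-means (k = 8 by default); gene-set enrichment is the exact upper-tail
hypergeometric test, fold = (k/n)/(K/N).

Every input the pipeline consumes can also be *generated*, with planted
ground truth, by `pantx.synthetic_fixtures` (CLI: `pantx fixtures`), so the
whole pipeline is testable offline.

## Worked example

```sh
pantx fixtures --scenario unify --seed 1 -o fx
pantx unify --base fx/base.fa --query fx/query.fa --hits fx/q_vs_b.psl \
    -o unified.fa --log decisions.tsv
```

prints

```
{"MERGE": 1, "REDUNDANT": 2, "UNIQUE": 3}
```

i.e. of the six query transcripts, one bridged two fragmented base
transcripts and was merged into the planted full-length gene
(`comp17000000_c0_seq1` in `unified.fa`, byte-identical to
`fx/truth_merged.fa`), two were redundant with base transcripts and
dropped, and three were genuinely new and added under the
`comp17010001+` locus range. `decisions.tsv` lists each query's category
with its anchors and scores.

```sh
pantx fixtures --scenario variants --seed 1 -o vfx
pantx variants --vcf vfx/variants.vcf -o vout
```

prints `12 records pass of 40` — the boundary-straddling records at e.g.
QUAL 39.9 or a 15 bp indel length difference fail, while QUAL 40.0 and
FS 60.0 pass; `vout/snp_intersections.tsv` holds the per-strain-subset SNP
counts.

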