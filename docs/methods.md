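# Methods

## The unification model

The package treats pan-transcriptome construction as a classification
problem over pairwise alignments. One assembly is designated *base* and is
always preferred: its sequence is kept verbatim wherever the two assemblies
overlap, and a query transcript that overlaps the base at all (any hit with
Blat score ≥ `min_score`) is discarded unless it can serve as a merge
bridge. This asymmetry is deliberate — the base assembly is assumed to be
the deeper or better-curated one — and it makes unification idempotent:
re-unifying the output against itself classifies every transcript as
redundant and changes nothing (asserted in the tests).

The Blat score is fixed as `matches − mismatches − qNumInsert −
tNumInsert`, the standard Blat web score; identity is
`matches / (matches + mismatches)`, with gap bases excluded from the
denominator. All internal coordinates are 0-based half-open; PSL is read
natively, tabular BLAST and VCF are converted at the file boundary.

### Two-anchor merging

A query bridges two base transcripts when, among its score-passing hits
(each with internal gaps ≤ `max_gap_bases` = 200):

* one hit covers the query's 5′ side and enters its target near the
  target's 3′ end, the other covers the 3′ side and enters its target near
  the target's 5′ end;
* the outer ends of the query leave ≤ `max_end_overhang` = 100 unmatched
  bases (de novo assembly ends are error-prone, so short overhangs are
  forgiven rather than treated as evidence of non-homology).

"Near an end" is quantified with the same 100 bp tolerance as the outer
overhangs; no separate threshold is introduced. When more than one anchor
pair qualifies, the pair with the largest summed hit score wins, ties
broken lexicographically on (anchor5, anchor3); hits on opposite strands
are never paired, and a minus-strand bridge is reverse-complemented before
assembly. The merged sequence is `anchor5[0:t_end5) +
bridge[q_end5:q_start3) + anchor3[t_start3:)`. If the two anchor hits
overlap on the bridge, the bridge contributes nothing and the anchors are
joined directly — but only when their sequences agree base-for-base across
the junction; disagreement is a hard "incompatible merge" error rather
than an arbitrary choice. Provenance is recorded per segment and must tile
the merged sequence exactly (asserted for every merge).

Anchors consumed by a merge are excluded from later merge candidacy within
the same run, but their hits still count as overlap for the
redundant/unique decision: a transcript redundant with a consumed anchor is
still redundant, since the anchor's sequence lives on inside the merged
record.

`unify()` needs all-vs-all alignments among the *added* transcripts to
cluster them into loci; since its interface takes only query-vs-base hits,
it computes these internally with the built-in k-mer aligner unless the
caller supplies them (`query_self_hits`).

### Locus clustering

BLASTClust-style single linkage: an edge requires one hit with identity
≥ 0.95 whose aligned span covers ≥ 20% of *both* members; loci are the
connected components. Coverage is evaluated per hit — multiple partial hits
between one pair are not summed, matching per-HSP behavior. Components are
ordered by each component's first member in input order, which makes the
naming deterministic and the result invariant to edge-list order.

## Naming

Three disjoint Trinity-style ranges: merged loci from comp17000000, added
loci from comp17010001, manual genes from comp17050001. The counter object
refuses to cross a range boundary, so collisions between categories are
structurally impossible rather than merely unlikely. Isoforms are numbered
`_seq1, _seq2, …` in input order within a locus.

## Decontamination

The three removal criteria are evaluated on locus representatives only and
cascade to all isoforms. The trusted-taxa test is a case-insensitive prefix
match on the organism string. A trusted *best* hit shields the transcript
from criteria 1–2 entirely; otherwise **any** non-trusted hit can trigger
removal (the alternative — testing only the best non-trusted hit — is a
plausible reading too; "any hit" is the stricter choice and is the one
implemented). "Similarity" for the protein criterion is read from the
positives-percent field when the hit table carries one, else from percent
identity. Thresholds are inclusive (≥ 0.95 removes). Removal is monotone:
raising a cutoff can only keep more transcripts (tested).

## Translation

Per frame, ORFs are maximal stop-free codon stretches. The stretch at the
frame's start needs no methionine; a stretch downstream of an in-frame stop
starts at its first ATG and is dropped if it has none. The interval of an
ORF includes its terminal stop codon when present; reverse-frame intervals
are reported on the forward strand with the frame sign carrying
orientation. Codons containing N translate to X and are never stops.

Frame choice: majority (≥ 2 of up to 3) among the top protein hits wins and
the chosen ORF must overlap the union of the agreeing hits' query intervals
by ≥ 1 nt; with no majority, the longest ORF overlapping any hit in that
hit's frame; with no hits, the longest ORF anywhere. Each stage falls
through to the next when it matches no ORF (the vote can name a frame whose
ORFs all miss the hit interval; falling through is the only option that
never fabricates a call). Ties between equal-length ORFs break by smaller
start, then frame order +1,+2,+3,−1,−2,−3.

Chimera screening applies to transcripts > 2000 bp whose longest ORF spans
< 80% of their length. Among the three longest ORFs, those ≥ 300 aa and
mutually non-overlapping (greedy by descending length) survive; with ≥ 2
survivors the transcript is cut at the midpoints between adjacent ORF
intervals. Midpoint cuts are the one splitting rule that conserves the
entire sequence deterministically; concatenating the parts reproduces the
original byte-for-byte (asserted).

## Variant filtering

SNP clauses: QUAL < 40, FS > 60, SOR > 3, MQ < 40. Indel clauses:
QUAL < 40, FS > 200. All comparisons are strict, so QUAL = 40.0 and
FS = 60.0 pass. A missing annotation never fails a record (the hard-filter
convention for absent annotations). The indel length rule is stated
ambiguously in its sources — "shorter than 15 bp kept" vs "15 bp and
shorter" — so the default removes |len(ref) − len(alt)| ≥ 15 and
`indel_max_len` can be set to 16 for the inclusive reading. Multi-allelic
rows are split per ALT; a strain carries a position if any non-reference
allele is called. Intersection counts are exact-membership counts over
every strain subset and are asserted to sum to the union on every call.
"SNPs per gene" can average over all genes or only covered genes (when a
coverage table is supplied); the mode is recorded in the output because
the two readings are both defensible.

## Expression conventions

Thresholds compare ≥ on the provided normalized counts with no rounding.
The unique-per-strain mode requires the read threshold in *all* of a
strain's designated exponential-growth samples; the designation (strain →
timepoint, default CCMP373/374 → day 2, CCMP2090 → day 1) is a parameter
because it encodes experimental design, not biology. Standardization uses
the sample standard deviation (ddof = 1); zero-variance rows become all
zeros and are logged rather than erroring, since constant genes are
uninformative but not invalid. K-means is Lloyd's algorithm with seeded
k-means++ initialization and Euclidean distance on standardized rows; the
original clustering tool's settings are unknown, so cluster memberships are
not expected to reproduce any particular published clustering even on
identical data. Enrichment is the exact hypergeometric upper tail via
`scipy.stats.hypergeom.sf`, checked in the tests against exhaustive
enumeration for all universes up to size 12.

## Synthetic data

The fixture generators emulate the *structure* of the real inputs, not
their scale or content:

* random sequence at 68% GC by default, echoing the organism's GC-rich
  genome;
* bridge scenarios plant a 3 kb gene split into a 1.4 kb 5′ fragment and a
  1.4 kb 3′ fragment with a 700 bp bridge spanning the 200 bp gap — sizes
  chosen so every merge threshold is exercised with room to spare;
* redundant queries are substrings mutated at ≤ 0.5% (within the observed
  0.3–0.5% per-base strain divergence band); unique queries are rejected
  until they share no 20-mer with the base;
* alignments come from a naive exact-k-mer chaining aligner (k = 20) that
  is *not* a Blat replacement: it handles exact and lightly mutated
  homology, which is all the planted scenarios contain. Real analyses
  consume real Blat/BLAST output;
* the variant generator writes records on both sides of every filter
  threshold and derives its truth by direct clause evaluation, so
  filter tests are truth-table comparisons, not spot checks;
* default problem sizes (50 base transcripts, 40 VCF records, 200 genes,
  ~20 transcripts in the ORF set) keep the full suite and the acceptance
  script fast while still covering every code path several times over.

What passing on these fixtures does **not** show: behavior on genuinely
diverged paralogs, repeat-heavy transcripts, or alignment artifacts that
a k-mer chainer cannot produce — real-data runs depend on the upstream
aligner's sensitivity. Categorical outputs on fixtures are asserted with
zero tolerance; there are no statistical pass bands.

## Known limitations

* Merging handles exactly two anchors; more-than-three-way merges are out
  of scope.
* The 12-column BLAST tabular format does not carry the query length, so
  minus-strand protein-hit frames are derived from the interval's
  forward-strand phase rather than from the 3′ end as BLAST itself counts
  them; fixture-generated hits use the package's convention consistently.
* Taxon screening matches organism-name prefixes; it does not resolve
  taxids against a taxonomy database.
* Only the standard genetic code is supported.
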