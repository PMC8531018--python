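"""Expression-side conventions: representative selection, expressed-gene
filtering, per-strain unique-expression partitions, gene-wise
standardization with k-means clustering, and hypergeometric gene-set
enrichment.

"Normalized reads" are consumed as given (library-size normalization is
upstream); thresholds compare >= with no rounding. Differential-expression
calling itself is likewise upstream — clustering accepts any gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io_model import ExpressionMatrix
from .locus_clustering import LocusCluster

logger = logging.getLogger(__name__)


@dataclass
class ExpressionFilterParams:
    """Expressed-gene thresholds.

    A gene is expressed when it has at least ``min_reads`` normalized reads
    in at least ``min_samples`` samples. In unique-per-strain mode the same
    read threshold is instead required in *all* of a strain's designated
    exponential-growth samples (both day-2 replicates, or the single
    non-infected day-1 sample, depending on the strain's experiment).
    """

    min_reads: float = 7.0
    min_samples: int = 3
    #: strain -> timepoint whose samples define exponential growth for the
    #: unique-per-strain comparison.
    unique_mode_timepoints: Mapping[str, str] = field(
        default_factory=lambda: {"CCMP373": "T2", "CCMP374": "T2", "CCMP2090": "T1"}
    )

    def __post_init__(self) -> None:
        if self.min_reads <= 0:
            raise ValueError("min_reads must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def select_representatives(
    loci: Sequence[LocusCluster] | Mapping[str, Sequence[str]],
    lengths: Mapping[str, int],
) -> dict[str, str]:
    """Representative per locus: the longest member, ties to the
    lexicographically smallest id."""
    if isinstance(loci, Mapping):
        items = loci.items()
    else:
        items = ((c.locus_id, c.member_ids) for c in loci)
    reps = {}
    for locus_id, members in items:
        if not members:
            raise ValueError(f"locus {locus_id!r} has no members")
        reps[locus_id] = min(members, key=lambda m: (-lengths[m], m))
    return reps


def filter_expressed(
    matrix: ExpressionMatrix, params: ExpressionFilterParams | None = None
) -> set[str]:
    """Gene ids with >= min_reads in >= min_samples samples."""
    params = params or ExpressionFilterParams()
    mask = (matrix.values >= params.min_reads).sum(axis=1) >= params.min_samples
    return {g for g, keep in zip(matrix.genes, mask) if keep}


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, set]:
    """Exact-membership partition of the union over all non-empty subsets.

    The regions are disjoint and cover the union (asserted on every call).
    """
    names = sorted(sets)
    if not names:
        raise ValueError("need at least one set")
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    union = set().union(*sets.values())
    for item in union:
        members = frozenset(n for n in names if item in sets[n])
        regions[members].add(item)
    assert sum(len(v) for v in regions.values()) == len(union)
    return regions


def unique_by_strain(
    matrix: ExpressionMatrix,
    params: ExpressionFilterParams | None = None,
    strains: Sequence[str] | None = None,
) -> tuple[dict[frozenset, set], dict[str, set]]:
    """Digital-Venn partition of genes expressed per strain in exponential
    growth.

    A gene counts as expressed in a strain when it has at least
    ``min_reads`` in every one of that strain's designated samples (the
    strain's exponential-growth timepoint per
    ``unique_mode_timepoints``; strains not listed there use all their
    samples). Returns the exact-membership regions and the per-strain sets.
    """
    params = params or ExpressionFilterParams()
    if strains is None:
        strains = sorted({s.strain for s in matrix.samples})
    per_strain: dict[str, set] = {}
    for strain in strains:
        wanted_tp = params.unique_mode_timepoints.get(strain)
        cols = [
            i
            for i, s in enumerate(matrix.samples)
            if s.strain == strain and (wanted_tp is None or s.timepoint == wanted_tp)
        ]
        if not cols:
            raise ValueError(f"strain {strain!r} has no qualifying samples")
        expressed = np.all(matrix.values[:, cols] >= params.min_reads, axis=1)
        per_strain[strain] = {g for g, e in zip(matrix.genes, expressed) if e}
    return venn_partition(per_strain), per_strain


def standardize_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores: each row to mean 0, sample standard deviation 1.

    Rows with zero variance are emitted as all zeros and logged.
    """
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    if degenerate.any():
        for g in np.asarray(matrix.genes)[degenerate]:
            logger.warning("gene %s has zero variance; standardized row set to 0", g)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[degenerate, :] = 0.0
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.genes = list(matrix.genes)
    out.samples = list(matrix.samples)
    out.values = z  # z-scores are signed; skip the >=0 input validation
    return out


def kmeans_clusters(
    standardized: ExpressionMatrix | np.ndarray,
    k: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """K-means (k-means++ init, Lloyd iterations) on standardized rows.

    Returns one cluster label per gene; deterministic for a given seed.
    """
    from sklearn.cluster import KMeans

    X = standardized.values if isinstance(standardized, ExpressionMatrix) else standardized
    if k > X.shape[0]:
        raise ValueError("k may not exceed the number of genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


@dataclass
class EnrichmentResult:
    fold_enrichment: float
    p_value: float
    k_overlap: int
    set_size: int
    cluster_size: int
    universe_size: int
    defined: bool = True


def hypergeom_enrichment(
    gene_set: set[str] | Sequence[str],
    cluster: set[str] | Sequence[str],
    universe_size: int,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene set in a cluster.

    With N the universe size, K the set size, n the cluster size and k their
    overlap: fold = (k/n)/(K/N) and p = P[X >= k] for X ~ Hypergeom(N, K, n).
    An empty set or cluster yields p = 1 with the fold undefined.
    """
    K = len(set(gene_set))
    n = len(set(cluster))
    k = len(set(gene_set) & set(cluster))
    N = universe_size
    if K == 0 or n == 0:
        return EnrichmentResult(float("nan"), 1.0, k, K, n, N, defined=False)
    fold = (k / n) / (K / N)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(fold, p, k, K, n, N)
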