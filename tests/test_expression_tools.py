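import random

import numpy as np
import pytest

from pantx.expression_tools import (
    ExpressionFilterParams,
    filter_expressed,
    hypergeom_enrichment,
    kmeans_clusters,
    select_representatives,
    standardize_by_gene,
    unique_by_strain,
    venn_partition,
)
from pantx.io_model import ExpressionMatrix, SampleMeta

from .oracles import exact_membership_counts_oracle, hypergeom_upper_tail_oracle


def _matrix(rows, genes=None, strains=None):
    rows = np.asarray(rows, dtype=float)
    n_s = rows.shape[1]
    samples = [
        SampleMeta(f"s{i}", (strains or ["X"] * n_s)[i], "T0") for i in range(n_s)
    ]
    return ExpressionMatrix(
        genes=genes or [f"g{i}" for i in range(rows.shape[0])],
        samples=samples,
        values=rows,
    )


class TestRepresentatives:
    def test_longest_wins(self):
        assert select_representatives({"L": ["a", "b"]}, {"a": 500, "b": 800}) == {"L": "b"}

    def test_tie_breaks_lexicographically(self):
        assert select_representatives({"L": ["b", "a"]}, {"a": 800, "b": 800}) == {"L": "a"}

    def test_singleton(self):
        assert select_representatives({"L": ["only"]}, {"only": 10}) == {"L": "only"}


class TestFilterExpressed:
    def test_boundary_row_passes(self):
        m = _matrix([[7, 7, 7, 0, 0, 0, 0, 0]])
        assert filter_expressed(m) == {"g0"}

    def test_two_high_samples_insufficient(self):
        m = _matrix([[100, 100, 6.9, 0, 0, 0, 0, 0]])
        assert filter_expressed(m) == set()

    def test_all_zero_not_expressed(self):
        m = _matrix([[0] * 8])
        assert filter_expressed(m) == set()

    def test_monotone_in_min_reads(self):
        rng = random.Random(0)
        m = _matrix([[rng.uniform(0, 20) for _ in range(6)] for _ in range(50)])
        prev = None
        for thresh in (1.0, 5.0, 7.0, 12.0):
            got = filter_expressed(m, ExpressionFilterParams(min_reads=thresh))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_planted_fixture_recovery(self, expression_fixture):
        fx = expression_fixture
        assert filter_expressed(fx.matrix) == fx.truth_expressed


class TestUniqueByStrain:
    def test_three_set_example(self):
        regions = venn_partition({"A": {"g1", "g2"}, "B": {"g2"}, "C": set()})
        assert regions[frozenset({"A"})] == {"g1"}
        assert regions[frozenset({"A", "B"})] == {"g2"}
        assert all(
            not v for k, v in regions.items() if k not in
            ({frozenset({"A"}), frozenset({"A", "B"})})
        )

    def test_gene_in_all_strains_in_triple_region_only(self):
        regions = venn_partition({"A": {"g"}, "B": {"g"}, "C": {"g"}})
        assert regions[frozenset({"A", "B", "C"})] == {"g"}
        assert sum(len(v) for v in regions.values()) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_regions_match_membership_oracle(self, seed):
        rng = random.Random(seed)
        sets = {
            s: {f"g{rng.randrange(300)}" for _ in range(rng.randint(0, 200))}
            for s in ("A", "B", "C")
        }
        regions = venn_partition(sets)
        assert {k: len(v) for k, v in regions.items()} == \
            exact_membership_counts_oracle(sets)

    def test_fixture_strain_sets_recovered(self, expression_fixture):
        fx = expression_fixture
        regions, per_strain = unique_by_strain(fx.matrix)
        assert per_strain == fx.truth_unique_sets
        union = set().union(*per_strain.values())
        assert sum(len(v) for v in regions.values()) == len(union)

    def test_strain_without_qualifying_samples_is_hard_error(self, expression_fixture):
        fx = expression_fixture
        with pytest.raises(ValueError, match="no qualifying samples"):
            unique_by_strain(fx.matrix, strains=["CCMP999"])

    def test_requires_threshold_in_all_designated_samples(self):
        samples = [
            SampleMeta("a", "CCMP373", "T2", "A"),
            SampleMeta("b", "CCMP373", "T2", "B"),
        ]
        m = ExpressionMatrix(genes=["g0"], samples=samples, values=[[100.0, 6.9]])
        _, sets = unique_by_strain(m, strains=["CCMP373"])
        assert sets["CCMP373"] == set()


class TestStandardize:
    def test_closed_form_row(self):
        z = standardize_by_gene(_matrix([[1, 2, 3]]))
        assert z.values[0] == pytest.approx([-1, 0, 1])

    def test_constant_row_becomes_zero(self):
        z = standardize_by_gene(_matrix([[5, 5, 5]]))
        assert np.all(z.values[0] == 0)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.uniform(0, 100, size=(40, 9)))
        z = standardize_by_gene(m)
        assert np.allclose(z.values.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-12)


class TestKmeans:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(30, 5)) + np.array([3, 3, 3, -3, -3])
        b = rng.normal(0, 0.1, size=(30, 5)) - np.array([3, 3, 3, -3, -3])
        X = np.vstack([a, b])
        labels = kmeans_clusters(X, k=2, seed=1)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_k_equals_n_gives_singletons(self):
        X = np.arange(12, dtype=float).reshape(6, 2) * 10
        labels = kmeans_clusters(X, k=6, seed=0)
        assert len(set(labels)) == 6

    def test_same_seed_identical_assignment(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        l1 = kmeans_clusters(X, k=8, seed=7)
        l2 = kmeans_clusters(X, k=8, seed=7)
        assert np.array_equal(l1, l2)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_clusters(np.zeros((3, 2)), k=4)


class TestHypergeom:
    def test_reference_case(self):
        r = hypergeom_enrichment({"a", "b", "c", "d", "e"}, {"a", "b", "c", "d"}, 10)
        assert r.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_fold_of_one_at_expectation(self):
        # N=10, K=5, n=4, k=2: k = n*K/N exactly
        gene_set = {"a", "b", "c", "d", "e"}
        cluster = {"a", "b", "x", "y"}
        r = hypergeom_enrichment(gene_set, cluster, 10)
        assert r.fold_enrichment == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        r = hypergeom_enrichment({"a"}, {"b"}, 10)
        assert r.p_value == pytest.approx(1.0)

    def test_empty_set_flagged_undefined(self):
        r = hypergeom_enrichment(set(), {"a"}, 10)
        assert not r.defined and r.p_value == 1.0

    def test_matches_enumeration_oracle_exhaustively(self):
        genes = [f"g{i}" for i in range(12)]
        for N in range(1, 13):
            universe = genes[:N]
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        gene_set = set(universe[:K])
                        cluster = set(universe[K - k : K - k + n]) if k else set(
                            universe[K : K + n]
                        )
                        if len(gene_set & cluster) != k or len(cluster) != n:
                            continue
                        if K == 0 or n == 0:
                            continue
                        r = hypergeom_enrichment(gene_set, cluster, N)
                        assert r.p_value == pytest.approx(
                            hypergeom_upper_tail_oracle(N, K, n, k), abs=1e-12
                        )
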