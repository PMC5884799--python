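from itertools import combinations
from math import comb

import numpy as np
import pytest

from consensusde.differential import bh_adjust
from consensusde.enrichment import (
    GeneSetCollection,
    hypergeometric_ora,
    pathway_zscore,
    pathway_zscore_counts,
    permutation_null,
    read_gene_sets,
)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by exact enumeration of favourable draw counts."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1)) / total


def collection(sets, universe):
    return GeneSetCollection(
        sets={t: frozenset(s) for t, s in sets.items()}, universe=frozenset(universe)
    )


class TestHypergeometricOra:
    def test_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = hypergeometric_ora({"g0", "g1"}, collection({"all": universe}, universe))
        assert res["p_hyper"].iloc[0] == pytest.approx(1.0)

    def test_exact_value_n10_k5(self):
        universe = [f"g{i}" for i in range(10)]
        term = set(universe[:5])
        panel = set(universe[:4])
        res = hypergeometric_ora(panel, collection({"t": term}, universe))
        assert res["p_hyper"].iloc[0] == pytest.approx(5 / 210)

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(universe, size=K, replace=False))
            panel = set(rng.choice(universe, size=n, replace=False))
            k = len(panel & term)
            res = hypergeometric_ora(panel, collection({"t": term}, universe))
            assert res["p_hyper"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), rel=1e-10
            )

    def test_zero_hits_complement_identity(self):
        # with k=0 the tail P(X >= 0) is 1; the complement of P(X >= 1) is
        # the probability of drawing no term gene, checked by brute force
        universe = [f"g{i}" for i in range(12)]
        term, panel = set(universe[:4]), set(universe[8:12])
        res = hypergeometric_ora(panel, collection({"t": term}, universe))
        assert res["p_hyper"].iloc[0] == pytest.approx(1.0)
        p_no_hit = sum(
            1 for draw in combinations(universe, 4) if not (set(draw) & term)
        ) / comb(12, 4)
        assert 1 - hypergeom_tail_oracle(1, 12, 4, 4) == pytest.approx(
            p_no_hit, rel=1e-12
        )

    def test_panel_genes_outside_universe_dropped(self):
        universe = {"a", "b", "c", "d"}
        res = hypergeometric_ora(
            {"a", "zz"}, collection({"t": {"a", "b"}}, universe)
        )
        assert res["n"].iloc[0] == 1

    def test_bh_column_matches_shared_adjuster(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = {
            f"t{j}": set(rng.choice(universe, size=8, replace=False)) for j in range(6)
        }
        panel = set(rng.choice(universe, size=10, replace=False))
        res = hypergeometric_ora(panel, collection(sets, universe))
        np.testing.assert_array_equal(
            res["p_adj"].to_numpy(), bh_adjust(res["p_hyper"].to_numpy())
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_ora({"a"}, collection({}, set()))


class TestPathwayZscore:
    def test_expected_count_centers_to_zero(self):
        # n·K/N = 10·10/100 = 1 hit exactly
        universe = [f"g{i}" for i in range(100)]
        term = set(universe[:10])
        panel = set(universe[9:19])  # one hit
        assert pathway_zscore(panel, term, universe) == pytest.approx(0.0)

    def test_direct_arithmetic_example(self):
        assert pathway_zscore_counts(5, 10, 10, 100) == pytest.approx(
            4.422166387140533, rel=1e-12
        )

    def test_degenerate_full_coverage_set_gives_zero(self):
        universe = {"a", "b", "c"}
        assert pathway_zscore({"a"}, universe, universe) == 0.0

    def test_antisymmetric_about_expectation(self, rng):
        for _ in range(20):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            mean = n * K / N
            lo = max(0, n + K - N)
            hi = min(n, K)
            k = int(rng.integers(lo, hi + 1))
            mirrored = 2 * mean - k
            if not (lo <= mirrored <= hi and abs(mirrored - round(mirrored)) < 1e-9):
                continue
            z1 = pathway_zscore_counts(k, n, K, N)
            z2 = pathway_zscore_counts(int(round(mirrored)), n, K, N)
            assert z1 == pytest.approx(-z2, abs=1e-9)

    def test_tiny_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_zscore_counts(0, 0, 0, 1)


class TestPermutationNull:
    def test_empty_term_set_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        p = permutation_null(5, set(), universe, n_perm=200, seed=1, observed_k=0)
        assert p == pytest.approx(1.0)

    def test_reproducible_from_seed(self):
        universe = [f"g{i}" for i in range(50)]
        term = set(universe[:8])
        kw = dict(n_perm=500, observed_k=4)
        assert permutation_null(10, term, universe, seed=42, **kw) == permutation_null(
            10, term, universe, seed=42, **kw
        )

    def test_converges_to_hypergeometric_tail(self, rng):
        for _ in range(5):
            N = int(rng.integers(30, 200))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(2, N // 2))
            n = int(rng.integers(2, N // 2))
            term = set(universe[:K])
            k_obs = int(rng.integers(0, min(n, K) + 1))
            p_perm = permutation_null(
                n, term, universe, n_perm=10_000, seed=7, observed_k=k_obs
            )
            p_hyper = hypergeom_tail_oracle(k_obs, N, K, n)
            se = np.sqrt(p_hyper * (1 - p_hyper) / 10_000) + 1 / 10_001
            assert abs(p_perm - p_hyper) < 3 * se + 1e-9

    def test_panel_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            permutation_null(5, {"a"}, {"a", "b"}, n_perm=100, observed_k=1)

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(1, {"a"}, {"a", "b"}, n_perm=10, observed_k=1)


class TestReadGeneSets:
    def test_gmt_parsing_and_universe_restriction(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "pathA\tdesc\tg1\tg2\tg3\npathB\tdesc\tg3\tg4\nsmall\tdesc\tg9\n"
        )
        coll = read_gene_sets(gmt, universe={"g1", "g2", "g3", "g4"}, min_size=2)
        assert set(coll.sets) == {"pathA", "pathB"}
        assert coll.sets["pathA"] == {"g1", "g2", "g3"}

    def test_default_universe_is_union_of_sets(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pathA\tdesc\tg1\tg2\npathB\tdesc\tg2\tg3\n")
        coll = read_gene_sets(gmt)
        assert coll.universe == {"g1", "g2", "g3"}
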