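"""Genomic clustering test: dedup rules, statistic, null, and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertescreen.clustering import (
    GeneLocus,
    load_and_dedupe,
    mc_pvalue,
    neighbor_count,
    permutation_null,
    run_test,
    z_score,
)
from vertescreen.synthetic import SimConfig, plant_clustered_targets, simulate_annotation


class TestLoadAndDedupe:
    def test_smallest_start_wins_on_duplicate_symbol(self):
        loci = load_and_dedupe([("A", "1", 500, 600), ("A", "1", 100, 200)])
        assert len(loci) == 1 and loci[0].start == 100

    def test_nonstandard_chromosome_dropped(self):
        loci = load_and_dedupe([("A", "MT", 1, 2), ("B", "chr2", 5, 9)])
        assert [l.symbol for l in loci] == ["B"]
        assert loci[0].chromosome == "2"

    def test_missing_coordinates_dropped(self):
        loci = load_and_dedupe([("A", "1", None, 5), ("B", "1", float("nan"), 5),
                                ("C", "1", 1, 5)])
        assert [l.symbol for l in loci] == ["C"]

    def test_nothing_left_is_an_error(self):
        with pytest.raises(ValueError):
            load_and_dedupe([("A", "MT", 1, 2)])


def _brute_force_count(targets, loci, window_bp):
    by_symbol = {l.symbol: l for l in loci}
    tl = [by_symbol[t] for t in targets]
    n = 0
    for a in tl:
        if any(
            b.symbol != a.symbol and b.chromosome == a.chromosome
            and abs(a.start - b.start) <= window_bp
            for b in tl
        ):
            n += 1
    return n


class TestNeighborCount:
    def test_single_target_has_no_neighbour(self):
        loci = [GeneLocus("A", "1", 10, 20), GeneLocus("B", "1", 30, 40)]
        assert neighbor_count({"A"}, loci, 10**6) == 0

    def test_boundary_distance_is_inclusive(self):
        loci = [GeneLocus("A", "1", 1, 10), GeneLocus("B", "1", 1_000_001, 1_000_010)]
        assert neighbor_count({"A", "B"}, loci, 1_000_000) == 2
        assert neighbor_count({"A", "B"}, loci, 999_999) == 0

    def test_different_chromosomes_never_neighbours(self):
        loci = [GeneLocus("A", "1", 100, 200), GeneLocus("B", "2", 100, 200)]
        assert neighbor_count({"A", "B"}, loci, 10**9) == 0

    def test_missing_target_reported(self):
        loci = [GeneLocus("A", "1", 10, 20)]
        with pytest.raises(ValueError, match="Zzz"):
            neighbor_count({"A", "Zzz"}, loci, 100)

    def test_equals_all_pairs_oracle_on_random_sets(self):
        cfg = SimConfig(seed=23, n_genes=200, n_target_genes=50,
                        n_planted_spatial_clusters=0)
        loci = simulate_annotation(cfg)
        symbols = [l.symbol for l in loci]
        rng = np.random.default_rng(23)
        for _ in range(50):
            k = int(rng.integers(2, 51))
            targets = set(rng.choice(symbols, size=k, replace=False))
            w = int(rng.choice([10**5, 10**6, 10**7, 5 * 10**7]))
            assert neighbor_count(targets, loci, w) == _brute_force_count(targets, loci, w)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10**7), st.integers(0, 10**7))
def test_neighbor_count_monotone_in_window(w1, w2):
    cfg = SimConfig(seed=29, n_genes=100, n_target_genes=30,
                    n_planted_spatial_clusters=0)
    loci = simulate_annotation(cfg)
    targets = {l.symbol for l in loci[:30]}
    lo, hi = sorted((w1, w2))
    assert neighbor_count(targets, loci, lo) <= neighbor_count(targets, loci, hi)


class TestPermutationNull:
    def test_saturating_window_counts_everyone(self):
        loci = [GeneLocus(f"G{i}", "1", 100 * i + 1, 100 * i + 10) for i in range(20)]
        counts, mean, sd = permutation_null(loci, k=5, window_bp=10**9, n_perm=20, seed=1)
        assert (counts == 5).all() and mean == 5.0 and sd == 0.0

    def test_zero_window_distinct_starts_counts_nobody(self):
        loci = [GeneLocus(f"G{i}", "1", 100 * i + 1, 100 * i + 10) for i in range(20)]
        counts, mean, _ = permutation_null(loci, k=5, window_bp=0, n_perm=20, seed=1)
        assert (counts == 0).all()

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=31, n_genes=100, n_target_genes=10,
                        n_planted_spatial_clusters=0)
        loci = simulate_annotation(cfg)
        a = permutation_null(loci, 20, 10**6, 50, seed=7)
        b = permutation_null(loci, 20, 10**6, 50, seed=7)
        assert np.array_equal(a[0], b[0]) and a[1:] == b[1:]

    def test_k_exceeding_universe_rejected(self):
        loci = [GeneLocus("A", "1", 1, 10)]
        with pytest.raises(ValueError):
            permutation_null(loci, k=2, window_bp=10, n_perm=5, seed=0)


class TestZAndP:
    @pytest.mark.parametrize("obs,mu,sd,expected", [
        (52, 36.70, 7.41, 2.07),
        (73, 62.72, 8.54, 1.20),
        (122, 113.17, 7.90, 1.12),
        (162, 156.04, 6.03, 0.99),
    ])
    def test_z_arithmetic(self, obs, mu, sd, expected):
        # mu and sd are quoted rounded to 2 dp, so the recomputed z can
        # differ from the quoted one by a unit in the last printed place
        assert z_score(obs, mu, sd) == pytest.approx(expected, abs=0.01)

    def test_z_degenerate_sd_flagged_not_raised(self):
        assert z_score(5, 5.0, 0.0) is None
        assert z_score(5, 5.0, 2.0) == 0.0

    def test_mc_pvalue_smoothing(self):
        assert mc_pvalue(100, np.zeros(999)) == pytest.approx(1 / 1000)
        assert mc_pvalue(0, np.ones(99)) == 1.0
        assert mc_pvalue(3, np.array([1, 2, 3, 4])) == pytest.approx(0.6)


class TestRunTest:
    def test_planted_clusters_detected_at_1mb(self):
        cfg = SimConfig(seed=37, n_genes=800, n_target_genes=100,
                        n_planted_spatial_clusters=10, genes_per_cluster=5,
                        cluster_span_bp=100_000)
        loci = simulate_annotation(cfg)
        loci, targets, _ = plant_clustered_targets(loci, cfg)
        results, meta = run_test(loci, targets, [10**6], n_perm=500, seed=37)
        assert results[0].p_mc <= 0.01
        assert results[0].observed >= 50

    def test_single_window_single_result_with_bonferroni(self):
        cfg = SimConfig(seed=41, n_genes=200, n_target_genes=30,
                        n_planted_spatial_clusters=0)
        loci = simulate_annotation(cfg)
        _, targets, _ = plant_clustered_targets(loci, cfg)
        results, meta = run_test(loci, targets, [10**6], n_perm=100, seed=1)
        assert len(results) == 1
        assert meta["bonferroni_alpha"] == pytest.approx(0.05)
        r = results[0]
        assert 0 <= r.observed <= r.n_targets
        assert 1 / (r.n_perm + 1) <= r.p_mc <= 1.0

    def test_null_pvalues_approximately_uniform(self):
        # targets drawn from the same universe as the permutations; the
        # 5 Mb window sits near half-saturation for 204 targets on this
        # genome, where the count distribution is widest and the +1-smoothed
        # p-value's tie-induced conservativeness is smallest
        cfg = SimConfig(seed=43, n_genes=2000, n_target_genes=204,
                        n_planted_spatial_clusters=0)
        loci = simulate_annotation(cfg)
        symbols = np.array([l.symbol for l in loci])
        rng = np.random.default_rng(43)
        pvals = []
        for rep in range(200):
            targets = set(rng.choice(symbols, size=204, replace=False))
            results, _ = run_test(loci, targets, [5 * 10**6], n_perm=200,
                                  seed=int(rng.integers(2**31)))
            pvals.append(results[0].p_mc)
        t = np.sort(np.array(pvals))
        n = len(t)
        ks = max(np.max(np.arange(1, n + 1) / n - t), np.max(t - np.arange(n) / n))
        assert ks < 0.15
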