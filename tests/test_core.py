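import numpy as np
import pytest
from scipy import stats

from sere.count_data import CountMatrix, DimensionError
from sere.core import (
    DegenerateInputError,
    DegenerateLaneError,
    EmptyComparisonError,
    bin_dispersions,
    expected_counts,
    pairwise_sere,
    sere_cluster,
    sere_confidence_interval,
    sere_statistic,
)
from sere.simulator import make_synthetic_pool, split_perfect_replicates

from .conftest import random_count_matrix
from .oracles import sere_oracle


class TestExpectedCounts:
    def test_hand_value_and_margin_preservation(self, toy_matrix):
        yhat = expected_counts(toy_matrix)
        assert np.allclose(yhat, [[8.0, 8.0], [6.0, 6.0]])
        assert np.allclose(yhat.sum(axis=1), toy_matrix.bin_totals)
        assert np.allclose(yhat.sum(axis=0), toy_matrix.lane_totals)

    def test_equal_lane_totals_split_each_bin_in_half(self, toy_matrix):
        yhat = expected_counts(toy_matrix)
        assert np.allclose(yhat[:, 0], toy_matrix.bin_totals / 2)

    def test_duplicated_lane_forces_identity(self):
        m = CountMatrix(
            bin_ids=["a", "b"], lane_ids=["c1", "c2"], counts=[[3, 3], [5, 5]]
        )
        assert np.allclose(expected_counts(m), m.counts)

    def test_zero_grand_total_rejected(self):
        m = CountMatrix(bin_ids=[], lane_ids=["x", "y"], counts=np.empty((0, 2), int))
        with pytest.raises(DegenerateInputError):
            expected_counts(m)


class TestBinDispersions:
    def test_hand_values(self, toy_matrix):
        assert np.allclose(bin_dispersions(toy_matrix), [1.0, 4.0 / 3.0])

    def test_singleton_with_equal_lane_totals_is_exactly_one(self, singleton_matrix):
        assert bin_dispersions(singleton_matrix)[0] == 1.0

    def test_duplicated_lanes_give_zero_everywhere(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 30, size=12)
        m = CountMatrix(
            bin_ids=[f"b{i}" for i in range(12)],
            lane_ids=["c1", "c2"],
            counts=np.stack([col, col], axis=1),
        )
        assert np.allclose(bin_dispersions(m), 0.0)

    def test_zero_total_bin_is_a_contract_violation(self):
        m = CountMatrix(bin_ids=["a", "b"], lane_ids=["x", "y"], counts=[[0, 0], [1, 2]])
        with pytest.raises(DegenerateInputError):
            bin_dispersions(m)


class TestSereStatistic:
    def test_hand_value(self, toy_matrix):
        result = sere_statistic(toy_matrix)
        assert result.s_squared == pytest.approx(7.0 / 6.0, abs=1e-12)
        assert result.sere == pytest.approx(np.sqrt(7.0 / 6.0), abs=1e-12)
        assert result.dof == 2 and result.n_used == 2

    def test_duplication_gives_exact_zero(self):
        rng = np.random.default_rng(11)
        col = rng.integers(0, 40, size=100)
        m = CountMatrix(
            bin_ids=[f"b{i}" for i in range(100)],
            lane_ids=["lane", "copy"],
            counts=np.stack([col, col], axis=1),
        )
        assert sere_statistic(m).sere == 0.0

    def test_singleton_neutrality_is_exact(self):
        rng = np.random.default_rng(21)
        base = CountMatrix(
            bin_ids=[f"b{i}" for i in range(30)],
            lane_ids=["x", "y"],
            counts=rng.integers(0, 12, size=(30, 2)) + 1,
        )
        singles = np.zeros((5, 2), dtype=int)
        singles[np.arange(5), rng.integers(0, 2, 5)] = 1
        extended = CountMatrix(
            bin_ids=list(base.bin_ids) + [f"s{i}" for i in range(5)],
            lane_ids=base.lane_ids,
            counts=np.vstack([base.counts, singles]),
        )
        a = sere_statistic(base, ci_level=None)
        b = sere_statistic(extended, ci_level=None)
        assert b.sere == a.sere
        assert b.n_singletons_excluded == 5

    def test_matches_brute_force_oracle_on_random_small_matrices(self):
        """Implementation agrees with a literal loop evaluation of the
        defining formulas over the small-matrix search space."""
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(400):
            m = random_count_matrix(rng)
            for exclude in (True, False):
                try:
                    expected = sere_oracle(m.counts, exclude_singletons=exclude)
                except ValueError:
                    with pytest.raises(
                        (EmptyComparisonError, DegenerateLaneError)
                    ):
                        sere_statistic(m, exclude_singletons=exclude, ci_level=None)
                    continue
                got = sere_statistic(m, exclude_singletons=exclude, ci_level=None)
                assert got.sere == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 300

    def test_single_lane_rejected(self):
        m = CountMatrix(bin_ids=["a"], lane_ids=["x"], counts=[[3]])
        with pytest.raises(DimensionError):
            sere_statistic(m)

    def test_zero_total_lane_rejected(self):
        m = CountMatrix(bin_ids=["a", "b"], lane_ids=["x", "y"], counts=[[1, 0], [4, 0]])
        with pytest.raises(DegenerateLaneError, match="y"):
            sere_statistic(m)

    def test_only_singletons_left_is_an_empty_comparison(self):
        m = CountMatrix(bin_ids=["a", "b"], lane_ids=["x", "y"], counts=[[1, 0], [0, 1]])
        with pytest.raises(EmptyComparisonError):
            sere_statistic(m)


class TestConfidenceInterval:
    def test_level_must_be_probability(self, toy_matrix):
        result = sere_statistic(toy_matrix)
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                sere_confidence_interval(result, level=bad)

    def test_null_mode_brackets_the_point_estimate(self, toy_matrix):
        result = sere_statistic(toy_matrix)
        lo, hi = sere_confidence_interval(result, mode="null")
        assert lo <= result.sere <= hi

    def test_noncentral_mode_contains_overdispersed_estimates(self, small_pool):
        lanes = split_perfect_replicates(small_pool, [50_000, 50_000], seed=8)
        result = sere_statistic(lanes)
        assert result.ci_lower <= max(result.sere, 1.0) <= result.ci_upper
        if result.sere >= 1.0:
            assert result.ci_lower <= result.sere <= result.ci_upper

    def test_width_shrinks_like_inverse_sqrt_dof(self):
        widths = {}
        for n in (100, 400):
            rng = np.random.default_rng(n)
            counts = rng.poisson(50, size=(n, 2))
            m = CountMatrix(
                bin_ids=[f"b{i}" for i in range(n)],
                lane_ids=["x", "y"],
                counts=counts,
            )
            result = sere_statistic(m, ci_mode="null")
            widths[n] = result.ci_upper - result.ci_lower
        # quadrupling dof should roughly halve the width
        assert widths[400] < widths[100]
        assert widths[100] / widths[400] == pytest.approx(2.0, rel=0.35)

    def test_interval_collapses_at_huge_dof(self):
        from sere.core import DispersionResult

        result = DispersionResult(
            per_bin_dispersion=np.ones(1),
            n_used=10**8,
            n_singletons_excluded=0,
            m_lanes=2,
            s_squared=1.0,
            sere=1.0,
            dof=10**8,
        )
        for mode in ("null", "noncentral"):
            lo, hi = sere_confidence_interval(result, mode=mode)
            assert hi - lo < 1e-3

    def test_null_calibration_of_scaled_dispersion(self):
        """Across repeated Poisson replicate pairs, nu*s^2 follows the
        chi-square law used by the interval construction."""
        rng = np.random.default_rng(2024)
        n_bins, n_sims = 200, 400
        lam = rng.uniform(20, 100, size=n_bins)
        samples = np.empty(n_sims)
        ids = [f"b{i}" for i in range(n_bins)]
        for s in range(n_sims):
            counts = rng.poisson(lam[:, None], size=(n_bins, 2))
            res = sere_statistic(
                CountMatrix(bin_ids=ids, lane_ids=["x", "y"], counts=counts),
                ci_level=None,
            )
            assert res.dof == n_bins  # no singletons at these rates
            samples[s] = res.dof * res.s_squared
        pvalue = stats.kstest(samples, stats.chi2(n_bins).cdf).pvalue
        assert pvalue > 0.01


class TestPairwise:
    def test_symmetry_zero_diagonal_and_duplicate_column(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 25, size=40)
        b = rng.integers(0, 25, size=40)
        m = CountMatrix(
            bin_ids=[f"b{i}" for i in range(40)],
            lane_ids=["a", "b", "a_copy"],
            counts=np.stack([a, b, a], axis=1),
        )
        pw = pairwise_sere(m)
        assert np.allclose(pw.values, pw.values.T)
        assert np.allclose(np.diag(pw.values), 0.0)
        assert pw.values[0, 2] == 0.0
        assert pw.values[0, 1] > 0.0

    def test_lane_permutation_permutes_the_matrix(self, small_pool):
        from sere.count_data import select_lanes

        m = split_perfect_replicates(small_pool, [30_000, 30_000, 30_000], seed=5)
        pw = pairwise_sere(m)
        order = ["lane3", "lane1", "lane2"]
        permuted = pairwise_sere(select_lanes(m, order))
        idx = [list(m.lane_ids).index(x) for x in order]
        assert np.allclose(permuted.values, pw.values[np.ix_(idx, idx)])

    def test_pairwise_tsv_round_trip(self, small_pool, tmp_path):
        import pandas as pd

        m = split_perfect_replicates(small_pool, [20_000, 20_000, 20_000], seed=6)
        pw = pairwise_sere(m)
        path = tmp_path / "pw.tsv"
        pw.to_tsv(path)
        df = pd.read_csv(path, sep="\t", index_col="lane")
        assert np.allclose(df.to_numpy(), pw.values)


class TestClustering:
    def test_duplicates_merge_at_height_zero(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 30, size=60)
        b = rng.integers(0, 30, size=60)
        m = CountMatrix(
            bin_ids=[f"b{i}" for i in range(60)],
            lane_ids=["a", "a_copy", "b"],
            counts=np.stack([a, a, b], axis=1),
        )
        dendrogram = sere_cluster(m)
        first_merge = dendrogram.linkage_matrix[0]
        assert first_merge[2] == 0.0
        assert sorted(first_merge[:2]) == [0, 1]

    def test_merge_heights_non_decreasing(self, small_pool):
        m = split_perfect_replicates(small_pool, [40_000] * 4, seed=3)
        z = sere_cluster(m).linkage_matrix
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_two_group_pools_cluster_by_group(self):
        """Replicates of two different abundance profiles: within-group
        merges sit near 1 (pure Poisson dispersion), the between-group
        merge clearly above."""
        from sere.simulator import synthetic_pool_pair

        pool_a, pool_b = synthetic_pool_pair(
            n_bins=3_000, pool_size=400_000, divergence=0.5, seed=99
        )
        lanes_a = split_perfect_replicates(pool_a, [80_000, 80_000], seed=1)
        lanes_b = split_perfect_replicates(pool_b, [80_000, 80_000], seed=2)
        m = CountMatrix(
            bin_ids=pool_a.bin_ids,
            lane_ids=["a1", "a2", "b1", "b2"],
            counts=np.hstack([lanes_a.counts, lanes_b.counts]),
        )
        z = sere_cluster(m).linkage_matrix
        within = z[:2, 2]
        between = z[2, 2]
        assert np.all(within < 1.1)
        assert between > 1.1
        assert np.all(within > 0.9)

    def test_fewer_than_three_lanes_rejected(self, toy_matrix):
        with pytest.raises(DimensionError):
            sere_cluster(toy_matrix)

    def test_newick_export_has_all_lane_tips(self, small_pool):
        m = split_perfect_replicates(small_pool, [30_000] * 3, seed=4)
        newick = sere_cluster(m).to_newick()
        assert newick.strip().endswith(";")
        for lane in m.lane_ids:
            assert str(lane) in newick


def test_null_pool_split_sere_is_near_one(small_pool):
    """Two disjoint draws from one pool are perfect replicates: the
    statistic should sit at 1 up to sampling noise."""
    seres = [
        sere_statistic(
            split_perfect_replicates(small_pool, [60_000, 60_000], seed=s),
            ci_level=None,
        ).sere
        for s in range(20)
    ]
    assert 0.99 < np.mean(seres) < 1.01
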