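"""Analysis statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from v1net import analysis
from v1net.analysis import (ResponseMatrix, cluster_and_sort,
                            correlated_pair_weight_share,
                            count_response_clusters, intensity_ramp,
                            mixture_regression_series, mixture_series,
                            rate_stats, reconstruct_rf, regress_mixture,
                            rf_pair_similarity, spontaneous_patterns,
                            transition_sharpness, weight_concentration,
                            weight_symmetry)
from v1net.engine import SpikeRaster
from v1net.stimuli import split_on_off


def rm_from(counts, dur=300):
    counts = np.asarray(counts, dtype=float)
    return ResponseMatrix(counts=counts,
                          stimulus_ids=np.arange(counts.shape[1]),
                          stim_duration=dur)


class TestReconstructRF:
    def test_on_equals_off_gives_zero_map(self):
        W = np.tile(np.random.default_rng(0).random(289), (3, 2))
        assert np.allclose(reconstruct_rf(W), 0.0)

    def test_single_on_weight(self):
        W = np.zeros((1, 578))
        W[0, 17 * 5 + 3] = 2.0
        rf = reconstruct_rf(W)
        assert rf[0, 5, 3] == 2.0 and rf.sum() == 2.0

    def test_roundtrip_with_on_off_split(self, rng):
        patch = rng.standard_normal((17, 17))
        rf = reconstruct_rf(split_on_off(patch)[None, :])
        assert np.allclose(rf[0], patch)

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_rf(np.zeros((3, 100)))


class TestWeightSymmetry:
    def test_symmetric_matrix_gives_one(self, rng):
        A = rng.random((6, 6))
        W = A + A.T
        assert weight_symmetry(W) == pytest.approx(1.0)

    def test_rank_reversed_pattern_gives_minus_one(self, rng):
        W = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        x = rng.random(len(iu[0]))
        W[iu] = x
        W[(iu[1], iu[0])] = 1.0 - x   # w_ji = 1 - w_ij
        assert weight_symmetry(W) == pytest.approx(-1.0)

    def test_matches_paired_entry_oracle(self, rng):
        W = rng.random((5, 5))
        np.fill_diagonal(W, 0.0)
        pairs_a, pairs_b = [], []
        for i in range(5):
            for j in range(5):
                if i != j:
                    pairs_a.append(W[i, j])
                    pairs_b.append(W[j, i])
        a, b = np.array(pairs_a), np.array(pairs_b)
        oracle = (((a - a.mean()) * (b - b.mean())).sum()
                  / np.sqrt(((a - a.mean()) ** 2).sum()
                            * ((b - b.mean()) ** 2).sum()))
        assert weight_symmetry(W) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_matrix_reported_undefined(self):
        assert np.isnan(weight_symmetry(np.ones((4, 4))))


class TestWeightConcentration:
    def test_full_fraction_is_one(self, rng):
        W = rng.random((10, 10))
        np.fill_diagonal(W, 0.0)
        assert weight_concentration(W, 1.0) == pytest.approx(1.0)

    def test_uniform_weights(self):
        W = np.ones((101, 101))
        np.fill_diagonal(W, 0.0)
        n = 101 * 100
        expected = np.ceil(0.1 * n) / n
        assert weight_concentration(W, 0.1) == pytest.approx(expected)

    def test_hand_computed_vector(self):
        assert weight_concentration(np.array([9.0, 1.0, 0.0, 0.0]),
                                    0.25) == pytest.approx(0.9)

    def test_zero_total_undefined(self):
        assert np.isnan(weight_concentration(np.zeros(5), 0.5))


class TestCorrelatedPairShare:
    def test_single_dominant_pair(self):
        counts = np.vstack([[1, 5, 2, 9], [1.1, 5, 2, 9.2],
                            [3, 0, 0, 1], [0, 2, 4, 0]])
        W = np.zeros((4, 4))
        W[0, 1] = 3.0
        W[1, 0] = 2.0   # all weight in the most correlated pair (0,1)
        share = correlated_pair_weight_share(rm_from(counts), W,
                                             top_pair_fraction=1 / 6)
        assert share == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_toy(self, rng):
        n = 6
        counts = rng.random((n, 20))
        W = rng.random((n, n))
        np.fill_diagonal(W, 0.0)
        frac = 0.3
        C = np.corrcoef(counts)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        pairs.sort(key=lambda p: -C[p])
        k = int(np.ceil(frac * len(pairs)))
        oracle = sum(W[i, j] + W[j, i] for i, j in pairs[:k]) / W.sum()
        assert correlated_pair_weight_share(
            rm_from(counts), W, frac) == pytest.approx(oracle, abs=1e-10)

    def test_random_weights_share_near_fraction(self, rng):
        """Weights independent of correlations: share ~ pair fraction."""
        n = 40
        shares = []
        for s in range(20):
            r = np.random.default_rng(s)
            counts = r.random((n, 30))
            W = r.random((n, n))
            np.fill_diagonal(W, 0.0)
            shares.append(correlated_pair_weight_share(rm_from(counts), W,
                                                       0.2))
        assert abs(np.mean(shares) - 0.2) < 0.03


class TestRFPairSimilarity:
    def test_identical_rfs(self, rng):
        row = rng.random(578)
        W_ff = np.tile(row, (6, 1))
        W = rng.random((6, 6))
        np.fill_diagonal(W, 0.0)
        assert rf_pair_similarity(W_ff, W, 0.2) == pytest.approx(1.0)

    def test_matches_enumeration_on_toy(self, rng):
        n = 4
        W_ff = rng.random((n, 578))
        W = rng.random((n, n))
        np.fill_diagonal(W, 0.0)
        rf = reconstruct_rf(W_ff).reshape(n, -1)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        pw = [W[i, j] + W[j, i] for i, j in pairs]
        frac = 0.5
        k = int(np.ceil(frac * len(pairs)))
        top = np.argsort(pw)[::-1][:k]
        cors = [np.corrcoef(rf[pairs[t][0]], rf[pairs[t][1]])[0, 1]
                for t in top]
        assert rf_pair_similarity(W_ff, W, frac) == pytest.approx(
            np.median(cors), abs=1e-10)


class TestClustering:
    def test_duplicate_columns_sort_adjacent(self, rng):
        base = rng.random((20, 6))
        base[:, 3] = base[:, 0]           # exact duplicate of column 0
        rm, C = cluster_and_sort(rm_from(base))
        pos = {int(s): k for k, s in enumerate(rm.stimulus_ids)}
        assert abs(pos[0] - pos[3]) == 1
        k0, k3 = pos[0], pos[3]
        assert C[k0, k3] == pytest.approx(1.0)

    def test_planted_partition_recovered(self, rng):
        a = np.array([5.0, 0, 5, 0, 5, 0, 5, 0] * 3)
        b = np.array([0.0, 5, 0, 5, 0, 5, 0, 5] * 3)
        cols = [a + 0.3 * rng.standard_normal(24) for _ in range(6)] + \
               [b + 0.3 * rng.standard_normal(24) for _ in range(6)]
        order = rng.permutation(12)
        M = np.column_stack([cols[k] for k in order])
        rm, C = cluster_and_sort(rm_from(M))
        labels = (order[rm.sort_order] < 6).astype(int)
        # groups are contiguous after leaf ordering
        assert len(np.flatnonzero(np.diff(labels) != 0)) == 1
        within = C[:6, :6][np.triu_indices(6, 1)].mean()
        between = C[:6, 6:].mean()
        assert within > between

    def test_column_permutation_invariance_of_cluster_count(self, rng):
        M = np.hstack([rng.random((15, 8)) + 3 * (k % 2) for k in range(4)])
        k1 = count_response_clusters(rm_from(M))
        k2 = count_response_clusters(rm_from(M[:, rng.permutation(32)]))
        assert k1 == k2

    def test_needs_two_presentations(self):
        with pytest.raises(ValueError):
            cluster_and_sort(rm_from(np.ones((5, 1))))


class TestSpontaneousPatterns:
    @staticmethod
    def make_raster(times, ids, duration, n_E=10):
        return SpikeRaster(times=np.asarray(times, dtype=np.int64),
                           neurons=np.asarray(ids, dtype=np.int32),
                           duration=duration, n_E=n_E, n_I=2)

    def test_dense_epoch_ranked_first(self):
        times = [10, 12, 14, 16, 18, 250]
        ids = [0, 1, 2, 3, 4, 5]
        M = spontaneous_patterns(self.make_raster(times, ids, 500),
                                 bin_ms=50, top_fraction=0.3)
        assert M.shape == (10, 3)
        assert M[:, 0].sum() == 5          # the dense first bin leads

    def test_tie_broken_by_earlier_bin(self):
        times = [260, 60]
        ids = [1, 1]
        M = spontaneous_patterns(self.make_raster(times, ids, 500),
                                 bin_ms=50, top_fraction=0.2)
        # equal totals: bin at 50-100 ms comes before bin at 250-300 ms
        assert M[1, 0] == 1 and M[1, 1] == 1

    def test_short_raster_rejected(self):
        with pytest.raises(ValueError):
            spontaneous_patterns(self.make_raster([1], [0], 20), bin_ms=50)


class TestMixtures:
    def test_endpoints_exact(self, rng):
        s1 = rng.standard_normal((17, 17))
        s2 = rng.standard_normal((17, 17))
        series = mixture_series(s1, s2, n=30)
        assert np.allclose(series[0], split_on_off(s2))
        assert np.allclose(series[-1], split_on_off(s1))

    def test_midpoint_blend_before_split(self, rng):
        s1 = rng.standard_normal((17, 17))
        s2 = rng.standard_normal((17, 17))
        series = mixture_series(s1, s2, n=31)
        assert np.allclose(series[15], split_on_off((s1 + s2) / 2))

    def test_component_intensities_monotone(self, rng):
        s1 = np.abs(rng.standard_normal((17, 17)))
        s2 = np.abs(rng.standard_normal((17, 17)))
        series = mixture_series(s1, s2, n=10)
        w1 = [float(v[:289].reshape(17, 17)[s1 > 1].sum()) for v in series]
        ramp = intensity_ramp(s1, n=10)
        tot = [v.sum() for v in ramp]
        assert np.all(np.diff(tot) > 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mixture_series(np.zeros((17, 17)), np.zeros((5, 5)))


class TestRegression:
    def test_orthogonal_pure_responses(self):
        r1 = np.array([1.0, 0, 0, 0])
        r2 = np.array([0.0, 1, 0, 0])
        assert regress_mixture(r1, r1, r2) == pytest.approx((1.0, 0.0))
        assert regress_mixture(r2, r1, r2) == pytest.approx((0.0, 1.0))

    def test_matches_normal_equations_oracle(self, rng):
        r1 = rng.random(30)
        r2 = 0.5 * r1 + rng.random(30)    # non-orthogonal regressors
        rn = rng.random(30)
        X = np.column_stack([r1 / np.linalg.norm(r1),
                             r2 / np.linalg.norm(r2)])
        y = rn / np.linalg.norm(rn)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        b1, b2 = regress_mixture(rn, r1, r2)
        assert (b1, b2) == pytest.approx(tuple(oracle), abs=1e-10)

    def test_zero_norm_response_warns(self):
        with pytest.warns(UserWarning):
            b = regress_mixture(np.zeros(5), np.ones(5), np.arange(5.0))
        assert b == (0.0, 0.0)

    def test_series_endpoints(self, rng):
        R = rng.random((12, 30)) + 0.1
        b1, b2 = mixture_regression_series(R)
        assert b1[-1] == pytest.approx(1.0, abs=1e-9)
        assert b2[0] == pytest.approx(1.0, abs=1e-9)


class TestTransitionSharpness:
    def test_linear_ramp(self):
        assert transition_sharpness(np.linspace(0, 1, 30)) == pytest.approx(
            1.0 / 29.0)

    def test_step_function(self):
        assert transition_sharpness(np.array([0.0] * 15 + [1.0] * 15)) == 1.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            transition_sharpness(np.array([1.0]))


class TestRateStats:
    def test_all_zero(self):
        assert rate_stats(rm_from(np.zeros((5, 4)))) == (0.0, 0.0, 0.0)

    def test_hand_computed_single_entry(self):
        med, mx, mm = rate_stats(rm_from(np.array([[10.0]]), dur=250))
        assert med == mx == mm == pytest.approx(40.0)

    def test_invariant_under_column_permutation(self, rng):
        M = rng.integers(0, 30, size=(20, 50)).astype(float)
        a = rate_stats(rm_from(M))
        b = rate_stats(rm_from(M[:, rng.permutation(50)]))
        assert a == b
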