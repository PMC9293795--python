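import numpy as np
import pytest

from _oracles import enumerate_signflip_null, flood_fill_clusters
from alphalat.permstats import (
    TFStatMap,
    corr_map,
    find_clusters,
    fisher_window_test,
    fisher_z,
    permtest_condition,
    permtest_correlation,
    permtest_cue_lateralization,
    pointwise_t,
    t_threshold,
)


class TestPointwiseT:
    def test_hand_computed(self):
        m = pointwise_t(np.array([1.0, 2.0, 3.0])[:, None, None])
        assert m.values[0, 0] == pytest.approx(3.4641, abs=1e-4)
        assert m.df == 2

    def test_zero_variance_flagged(self):
        m = pointwise_t(np.zeros((4, 2, 2)))
        assert np.all(np.isnan(m.values))

    def test_paired_identical_conditions_subthreshold_everywhere(self, rng):
        a = rng.standard_normal((5, 3, 3))
        m = pointwise_t(a, mode="paired", values_b=a.copy())
        assert find_clusters(m) == []

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            pointwise_t(np.zeros((1, 2, 2)))


class TestFindClusters:
    def test_all_subthreshold_empty(self):
        m = TFStatMap(values=np.full((4, 4), 0.5), df=10)
        assert find_clusters(m) == []

    def test_single_point_cluster(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 3.0
        clusters = find_clusters(TFStatMap(values=vals, df=10),
                                 threshold=2.5)
        assert len(clusters) == 1
        assert clusters[0].stat == pytest.approx(3.0)
        assert clusters[0].sign == 1

    def test_diagonal_points_are_two_clusters(self):
        vals = np.zeros((3, 3))
        vals[0, 0] = 3.0
        vals[1, 1] = 4.0
        clusters = find_clusters(vals, threshold=2.5)
        assert len(clusters) == 2

    def test_signs_clustered_separately(self):
        vals = np.array([[3.0, -3.0, 3.0]])
        clusters = find_clusters(vals, threshold=2.5)
        assert len(clusters) == 3
        assert sorted(c.sign for c in clusters) == [-1, 1, 1]

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(777)
        for _ in range(100):
            vals = rng.standard_normal((8, 8)) * 2.0
            got = find_clusters(vals, threshold=1.5)
            want = flood_fill_clusters(vals, 1.5)
            got_set = {(frozenset(map(tuple, np.argwhere(c.mask))),
                        round(c.stat, 9)) for c in got}
            want_set = {(m, round(s, 9)) for m, s, _ in want}
            assert got_set == want_set


class TestConditionPermutation:
    def test_identical_maps_give_no_clusters(self, rng):
        a = rng.standard_normal((6, 4, 5))
        res = permtest_condition(a, a.copy(), np.arange(4), np.arange(5),
                                 n_perm=50, seed=0)
        assert res.clusters == []

    def test_exact_null_matches_enumeration(self, rng):
        """Engine's sign-flip null equals brute-force enumeration exactly."""
        a = rng.standard_normal((4, 3, 3)) + 1.0
        b = rng.standard_normal((4, 3, 3))
        res = permtest_condition(a, b, np.arange(3), np.arange(3), exact=True)
        thresh = t_threshold(3, 0.05)
        want = enumerate_signflip_null(a - b, thresh)
        assert res.n_perm == 16
        assert np.allclose(np.sort(res.null_max_stats), np.sort(want),
                           atol=1e-9)

    def test_label_flip_negates_observed_map(self, rng):
        a = rng.standard_normal((5, 3, 4)) + 0.5
        b = rng.standard_normal((5, 3, 4))
        r1 = permtest_condition(a, b, np.arange(3), np.arange(4),
                                n_perm=10, seed=1)
        r2 = permtest_condition(b, a, np.arange(3), np.arange(4),
                                n_perm=10, seed=1)
        assert np.allclose(r1.extra["observed_map"],
                           -r2.extra["observed_map"], equal_nan=True)

    def test_deterministic_under_seed(self, rng):
        a = rng.standard_normal((6, 4, 5)) + 0.4
        b = rng.standard_normal((6, 4, 5))
        r1 = permtest_condition(a, b, np.arange(4), np.arange(5),
                                n_perm=100, seed=42)
        r2 = permtest_condition(a, b, np.arange(4), np.arange(5),
                                n_perm=100, seed=42)
        assert np.array_equal(r1.null_max_stats, r2.null_max_stats)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_strong_effect_hits_p_floor(self, rng):
        # enough subjects that no sampled sign pattern reproduces the
        # all-same-sign observed configuration
        a = rng.standard_normal((16, 4, 6)) * 0.1 + 2.0
        b = rng.standard_normal((16, 4, 6)) * 0.1
        res = permtest_condition(a, b, np.arange(4), np.arange(6),
                                 n_perm=200, seed=3)
        assert res.min_p == pytest.approx(1.0 / 201.0)


class TestCuePermutation:
    def _study(self, rng, li=0.0, n_subj=6, n_tr=40, nf=4, nt=20):
        pcs, pis = [], []
        for _ in range(n_subj):
            base = rng.gamma(3.0, 1.0, size=(n_tr, 1, nf, nt))
            noise = rng.lognormal(0.0, 0.5, size=(2, n_tr, 1, nf, nt))
            pcs.append(base * (1 - li) * noise[0])
            pis.append(base * (1 + li) * noise[1])
        return pcs, pis

    def test_strong_lateralization_hits_p_floor(self, rng):
        pcs, pis = self._study(rng, li=0.4, n_subj=8)
        res = permtest_cue_lateralization(pcs, pis, np.arange(4),
                                          np.arange(20), n_perm=100, seed=5,
                                          smooth_window=5)
        assert res.min_p == pytest.approx(1.0 / 101.0)
        top = res.clusters[0]
        assert top.sign == 1  # ipsilateral power dominates

    def test_deterministic_under_seed(self, rng):
        pcs, pis = self._study(rng, li=0.1)
        kw = dict(n_perm=50, seed=9, smooth_window=5)
        r1 = permtest_cue_lateralization(pcs, pis, np.arange(4),
                                         np.arange(20), **kw)
        r2 = permtest_cue_lateralization(pcs, pis, np.arange(4),
                                         np.arange(20), **kw)
        assert np.array_equal(r1.null_max_stats, r2.null_max_stats)

    def test_zero_iterations_rejected(self, rng):
        pcs, pis = self._study(rng)
        with pytest.raises(ValueError):
            permtest_cue_lateralization(pcs, pis, np.arange(4),
                                        np.arange(20), n_perm=0)

    def test_single_subject_rejected(self, rng):
        pcs, pis = self._study(rng, n_subj=1)
        with pytest.raises(ValueError):
            permtest_cue_lateralization(pcs, pis, np.arange(4),
                                        np.arange(20), n_perm=10)


class TestCorrelation:
    def test_constant_dauc_rejected(self, rng):
        with pytest.raises(ValueError):
            corr_map(rng.standard_normal((5, 2, 2)), np.full(5, 3.0))

    def test_exact_linear_coupling_gives_r_one(self):
        y = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        template = np.full((3, 4), 2.0)
        x = y[:, None, None] * template
        r = corr_map(x, y).values
        assert np.allclose(r, 1.0)

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            corr_map(rng.standard_normal((2, 2, 2)), np.array([1.0, 2.0]))

    def test_perfect_coupling_hits_p_floor(self, rng):
        y = rng.standard_normal(12)
        x = y[:, None, None] * np.ones((4, 5)) + 0.01 * rng.standard_normal(
            (12, 4, 5))
        res = permtest_correlation(x, y, np.arange(4), np.arange(5),
                                   n_perm=150, seed=2)
        assert res.min_p == pytest.approx(1.0 / 151.0)

    def test_deterministic_null(self, rng):
        y = rng.standard_normal(10)
        x = rng.standard_normal((10, 3, 4))
        r1 = permtest_correlation(x, y, np.arange(3), np.arange(4),
                                  n_perm=80, seed=6)
        r2 = permtest_correlation(x, y, np.arange(3), np.arange(4),
                                  n_perm=80, seed=6)
        assert np.array_equal(r1.null_max_stats, r2.null_max_stats)


class TestFisherWindow:
    def test_fisher_z_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(-0.5) == pytest.approx(-0.5493, abs=1e-4)
        assert fisher_z(0.0) == 0.0

    def test_zero_correlations_flagged(self):
        r = np.zeros((3, 5, 100))
        freqs = np.linspace(8, 14, 5)
        times = np.linspace(0, 2600, 100)
        res = fisher_window_test(r, freqs, times)
        assert res.t == 0.0
        assert res.flagged

    def test_unit_correlation_flagged(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.5, 0.5, (3, 5, 100))
        r[0, 2, 10] = 1.0
        res = fisher_window_test(r, np.linspace(8, 14, 5),
                                 np.linspace(0, 2600, 100))
        assert res.flagged
        assert np.isfinite(res.t)

    def test_in_window_excess_detected(self, rng):
        freqs = np.linspace(2, 20, 10)
        times = np.linspace(-500, 3200, 150)
        r = 0.05 * rng.standard_normal((3, 10, 150))
        win = ((times >= 870) & (times <= 1535))[None, :] \
            & ((freqs >= 8) & (freqs <= 14))[:, None]
        r += 0.5 * win
        res = fisher_window_test(r, freqs, times)
        assert res.df == 2
        assert res.t > 0
        assert np.all(res.z_in > res.z_out)
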