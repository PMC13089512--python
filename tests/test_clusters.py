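"""Cluster-based permutation inference: adjacency, paired and correlation tests."""

import numpy as np
import pytest

import mne
from remfrag.clusters import (
    adjacency_from_positions,
    pearson_r,
    tf_cluster_test,
    topo_cluster_correlation,
    topo_cluster_test,
)
from remfrag.io import CH_NAMES_19, POSTERIOR_CHANNELS


class TestAdjacency:
    def test_structure(self, adjacency):
        m = adjacency.matrix
        assert np.array_equal(m, m.T)
        assert not np.any(np.diag(m))
        assert adjacency.isolated == []
        assert np.median(m.sum(axis=1)) >= 5

    def test_posterior_channels_connected(self, adjacency):
        idx = {c: i for i, c in enumerate(adjacency.ch_names)}
        post = [idx[c] for c in POSTERIOR_CHANNELS]
        sub = adjacency.matrix[np.ix_(post, post)]
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(sub[u]):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert len(seen) == len(post)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestTopoClusterTest:
    def test_uniform_effect_forms_whole_scalp_cluster(self, adjacency, rng):
        maps = 2.0 + 0.2 * rng.standard_normal((12, 19))
        res = topo_cluster_test(maps, adjacency, n_permutations=500, seed=1)
        sig = res.significant()
        assert len(sig) == 1
        assert sig[0].sign == 1
        assert len(sig[0].members) == 19

    def test_identical_zero_maps_give_empty_result(self, adjacency):
        res = topo_cluster_test(np.zeros((8, 19)), adjacency,
                                n_permutations=200, seed=0)
        assert res.clusters == ()

    def test_focal_effect_stays_local(self, adjacency, rng):
        idx = {c: i for i, c in enumerate(adjacency.ch_names)}
        post = [idx[c] for c in POSTERIOR_CHANNELS]
        maps = 0.3 * rng.standard_normal((15, 19))
        maps[:, post] += 2.0
        res = topo_cluster_test(maps, adjacency, n_permutations=500, seed=2)
        sig = [c for c in res.significant() if c.sign == 1]
        assert sig
        allowed = set(post)
        for p in post:
            allowed |= set(np.flatnonzero(adjacency.matrix[p]))
        assert set(sig[0].members.tolist()) <= allowed

    def test_seed_reproducibility_and_add_one_rule(self, adjacency, rng):
        maps = rng.standard_normal((10, 19)) + 1.0
        a = topo_cluster_test(maps, adjacency, n_permutations=300, seed=42)
        b = topo_cluster_test(maps, adjacency, n_permutations=300, seed=42)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]
        assert all(c.p >= 1 / 301 for c in a.clusters)

    def test_membership_invariant_under_channel_reorder(self, adjacency, rng):
        maps = rng.standard_normal((10, 19))
        maps[:, :5] += 1.5
        order = list(rng.permutation(19))
        res_a = topo_cluster_test(maps, adjacency, n_permutations=200, seed=7)
        res_b = topo_cluster_test(maps[:, order], adjacency.reorder(order),
                                  n_permutations=200, seed=7)
        masses_a = sorted(round(c.mass, 9) for c in res_a.clusters)
        masses_b = sorted(round(c.mass, 9) for c in res_b.clusters)
        assert masses_a == masses_b
        names = lambda res, adj: sorted(
            tuple(sorted(adj.ch_names[i] for i in c.members)) for c in res.clusters)
        assert names(res_a, adjacency) == names(res_b, adjacency.reorder(order))


class TestTfClusterTest:
    def _maps(self, rng, n_sub=10, n_f=20, n_t=60, effect=0.0):
        maps = rng.standard_normal((n_sub, n_f, n_t))
        maps[:, 5:12, 30:50] += effect
        return maps

    def test_identical_zero_maps_empty(self):
        times = np.linspace(-3000, 15000, 60)
        freqs = np.linspace(5, 40, 20)
        res = tf_cluster_test(np.zeros((6, 20, 60)), times, freqs,
                              n_permutations=100, seed=0)
        assert res.clusters == ()

    def test_planted_blob_recovered(self, rng):
        times = np.linspace(-3000, 15000, 60)
        freqs = np.linspace(5, 40, 20)
        maps = self._maps(rng, effect=1.5)
        res = tf_cluster_test(maps, times, freqs, n_permutations=300, seed=3)
        sig = [c for c in res.significant() if c.sign == 1]
        assert sig
        members = set(map(tuple, sig[0].members.tolist()))
        post_cols = np.flatnonzero((times >= 0) & (times <= 14000))
        blob = {(f, np.searchsorted(post_cols, t))
                for f in range(5, 12) for t in range(30, 50)}
        blob = {(f, t - post_cols[0]) for f in range(5, 12) for t in range(30, 50)}
        overlap = len(members & blob) / len(blob)
        assert overlap >= 0.8

    def test_matches_mne_cluster_engine_on_shared_threshold(self, rng):
        """Cross-check cluster formation and masses against mne's engine."""
        from scipy import stats

        times = np.linspace(-3000, 15000, 40)
        freqs = np.linspace(5, 40, 12)
        maps = rng.standard_normal((9, 12, 40))
        maps[:, 3:7, 25:35] += 1.2
        res = tf_cluster_test(maps, times, freqs, baseline_window_ms=(-2000, -1000),
                              test_window_ms=(0, 14000), n_permutations=200, seed=5)
        # mne on the identically pre-processed difference maps
        bmask = (times >= -2000) & (times <= -1000)
        wmask = (times >= 0) & (times <= 14000)
        D = maps[:, :, wmask] - maps[:, :, bmask].mean(axis=2, keepdims=True)
        thr = stats.t.ppf(1 - 0.025, df=8)
        t_obs, mne_clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
            D, threshold=thr, n_permutations=100, tail=0, out_type="mask",
            seed=1, verbose="error")
        mne_masses = sorted(round(abs(t_obs[m].sum()), 6) for m in mne_clusters)
        our_masses = sorted(round(abs(c.mass), 6) for c in res.clusters)
        assert our_masses == mne_masses

    def test_permutation_p_converges_across_seeds(self, rng):
        times = np.linspace(-3000, 15000, 40)
        freqs = np.linspace(5, 40, 10)
        maps = rng.standard_normal((8, 10, 40))
        maps[:, 2:5, 20:30] += 1.0
        ps = []
        for seed in range(5):
            res = tf_cluster_test(maps, times, freqs, n_permutations=800, seed=seed)
            ps.append(res.clusters[0].p)
        p = np.mean(ps)
        assert np.std(ps) <= 3 * np.sqrt(p * (1 - p) / 800)


class TestTopoClusterCorrelation:
    def test_perfect_coupling_detected(self, adjacency, rng):
        maps = rng.standard_normal((12, 19))
        behavior = maps[:, 7].copy()
        res = topo_cluster_correlation(maps, behavior, adjacency,
                                       n_permutations=400, seed=0)
        sig = res.significant()
        assert sig
        assert 7 in set(np.concatenate([np.atleast_1d(c.members) for c in sig]))

    def test_cluster_mean_r_reported(self, adjacency, rng):
        maps = rng.standard_normal((14, 19))
        sig_source = rng.standard_normal(14)
        maps[:, :6] += sig_source[:, None]
        behavior = sig_source + 0.3 * rng.standard_normal(14)
        res = topo_cluster_correlation(maps, behavior, adjacency,
                                       n_permutations=400, seed=1)
        assert res.clusters
        top = res.clusters[0]
        mean_map = maps[:, top.members].mean(axis=1)
        assert top.cluster_mean_r == pytest.approx(pearson_r(mean_map, behavior))

    def test_constant_behavior_rejected(self, adjacency, rng):
        with pytest.raises(ValueError):
            topo_cluster_correlation(rng.standard_normal((8, 19)), np.ones(8),
                                     adjacency, n_permutations=50)

    def test_too_few_subjects_rejected(self, adjacency, rng):
        with pytest.raises(ValueError):
            topo_cluster_correlation(rng.standard_normal((3, 19)),
                                     np.arange(3.0), adjacency)
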