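"""Correlation-distance k-means, k selection, diagnostics and matching."""

import itertools
import warnings

import numpy as np
import pytest

from capdyn.clustering import (
    CoactivationPatterns,
    KSelectionCurve,
    _standardize_rows,
    assign_states,
    centroid_similarity_matrix,
    cluster_validity_index,
    concat_frames,
    frame_centroid_similarity,
    kmeans_caps,
    label_caps_by_network,
    match_clusters,
    scan_k,
    select_k_elbow,
    silhouette_by_cluster,
)
from capdyn.atlas import default_parcel_table
from capdyn.io import RoiTimeSeries, zscore_session
from capdyn.metrics import StateSequence
from capdyn.synthetic import MarkovParams, make_state_patterns, simulate_session


def _pool_from(frames):
    import pandas as pd

    frames = np.asarray(frames, dtype=float)
    im = pd.DataFrame(
        dict(
            subject_id="s1",
            group="HC",
            timepoint="baseline",
            run_index=0,
            frame_index=range(len(frames)),
        )
    )
    from capdyn.clustering import FramePool

    return FramePool(frames=frames, index_map=im)


def _exhaustive_best_bipartition(frames):
    """Brute-force optimum over all 2-partitions: centroid = mean of the
    standardized member frames, objective = total correlation distance."""
    Xs = _standardize_rows(frames)
    n, m = Xs.shape
    best_obj, best_part = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        lab = np.array((0,) + bits)
        if lab.min() == lab.max():
            continue
        obj = 0.0
        for g in (0, 1):
            mem = Xs[lab == g]
            c = _standardize_rows(mem.mean(0, keepdims=True), "centroid")
            obj += (1 - mem @ c[0] / m).sum()
        if obj < best_obj:
            best_obj, best_part = obj, lab
    return best_obj, best_part


class TestKMeans:
    def _two_pattern_frames(self, rng):
        a = np.concatenate([np.ones(10), -np.ones(10)])
        b = np.concatenate([np.ones(5), -np.ones(10), np.ones(5)])
        frames = np.array([a] * 4 + [b] * 4) + rng.normal(0, 0.05, (8, 20))
        return frames

    def test_matches_exhaustive_partition_oracle(self, rng):
        frames = self._two_pattern_frames(rng)
        pool = _pool_from(frames)
        res = kmeans_caps(pool, 2, n_replicates=10, seed=0)
        best_obj, best_part = _exhaustive_best_bipartition(frames)
        assert res.objective == pytest.approx(best_obj, abs=1e-8)
        same = np.array_equal(res.labels - 1, best_part)
        flipped = np.array_equal(2 - res.labels, best_part)
        assert same or flipped

    def test_objective_recomputable(self, rng):
        pool = _pool_from(rng.normal(size=(30, 12)))
        res = kmeans_caps(pool, 3, n_replicates=5, seed=1)
        assert res.recompute_objective() == pytest.approx(res.objective, abs=1e-8)
        assert np.bincount(res.labels, minlength=4)[1:].min() > 0

    def test_scale_invariance(self, rng):
        frames = self._two_pattern_frames(rng)
        scaled = frames * rng.uniform(0.5, 5.0, (8, 1))
        r1 = kmeans_caps(_pool_from(frames), 2, n_replicates=5, seed=2)
        r2 = kmeans_caps(_pool_from(scaled), 2, n_replicates=5, seed=2)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_determinism(self, rng):
        pool = _pool_from(rng.normal(size=(40, 10)))
        r1 = kmeans_caps(pool, 3, n_replicates=4, seed=9)
        r2 = kmeans_caps(pool, 3, n_replicates=4, seed=9)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.objective == r2.objective
        assert r1.replicate_scores == r2.replicate_scores

    def test_zero_variance_frame_rejected(self, rng):
        frames = rng.normal(size=(10, 5))
        frames[3] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            kmeans_caps(_pool_from(frames), 2, n_replicates=2, seed=0)


class TestCVI:
    def test_perfect_clusters_zero(self):
        base = np.vstack([np.tile([1.0, -1, 1, -1, 1, -1], (5, 1)),
                          np.tile([1.0, 1, -1, -1, 1, 1], (5, 1))])
        pool = _pool_from(base)
        res = kmeans_caps(pool, 2, n_replicates=3, seed=0)
        assert cluster_validity_index(pool, res) == pytest.approx(0.0, abs=1e-12)

    def test_separated_beats_noisy_merge(self, rng):
        a = np.concatenate([np.ones(8), -np.ones(8)])
        b = np.concatenate([-np.ones(8), np.ones(8)])
        tight = np.array([a] * 10 + [b] * 10) + rng.normal(0, 0.05, (20, 16))
        blurred = np.array([a] * 10 + [b] * 10) + rng.normal(0, 2.0, (20, 16))
        cvi_tight = cluster_validity_index(
            _pool_from(tight), kmeans_caps(_pool_from(tight), 2, n_replicates=5, seed=0)
        )
        cvi_blur = cluster_validity_index(
            _pool_from(blurred), kmeans_caps(_pool_from(blurred), 2, n_replicates=5, seed=0)
        )
        assert cvi_tight < cvi_blur

    def test_duplicate_centroids_flagged(self, rng):
        pool = _pool_from(rng.normal(size=(12, 8)))
        res = kmeans_caps(pool, 2, n_replicates=3, seed=0)
        res.centroids = np.vstack([res.centroids[0], res.centroids[0] + 1e-9])
        with pytest.warns(UserWarning, match="near-duplicate"):
            cluster_validity_index(pool, res)

    def test_k1_rejected(self, rng):
        pool = _pool_from(rng.normal(size=(12, 8)))
        res = kmeans_caps(pool, 2, n_replicates=2, seed=0)
        res.k = 1
        with pytest.raises(ValueError, match="k >= 2"):
            cluster_validity_index(pool, res)


class TestElbow:
    def test_constructed_elbow_at_six(self):
        ks = list(range(2, 13))
        scores = [(-1.0 * k if k <= 6 else -6.0 - 0.01 * (k - 6)) for k in ks]
        curve = KSelectionCurve(ks, scores)
        assert select_k_elbow(curve) == 6
        assert not curve.elbow_fit["ambiguous"]

    def test_linear_curve_ambiguous(self):
        ks = list(range(2, 10))
        curve = KSelectionCurve(ks, [-1.0 * k for k in ks])
        with pytest.warns(UserWarning, match="ambiguous"):
            k = select_k_elbow(curve)
        assert k == 2 and curve.elbow_fit["ambiguous"]

    def test_scan_determinism_and_bookkeeping(self, rng):
        frames = rng.normal(size=(60, 10))
        pool = _pool_from(frames)
        c1 = scan_k(pool, 2, 4, n_replicates=3, seed=0)
        c2 = scan_k(pool, 2, 4, n_replicates=3, seed=0)
        assert c1.k_values == [2, 3, 4] and len(c1.cvi_scores) == 3
        assert c1.cvi_scores == c2.cvi_scores

    @pytest.mark.parametrize("k_true", [4, 5, 6])
    def test_recovers_planted_state_count(self, k_true):
        """Scan + elbow recover the planted number of states on simulated
        sessions, across 10 seeds (allow one failure)."""
        table = default_parcel_table(90, 10)
        hits = 0
        for seed in range(10):
            ps = make_state_patterns(k_true, table, seed=seed)
            P = np.full((k_true, k_true), 0.4 / (k_true - 1))
            np.fill_diagonal(P, 0.6)
            mk = MarkovParams(np.full(k_true, 1 / k_true), P)
            sessions = []
            for s in range(6):
                ts, _ = simulate_session(
                    ps, mk, 100, n_runs=1, noise_sigma=1.0, seed=1000 * seed + s,
                    subject_id=f"s{s}",
                )
                sessions.append(zscore_session(ts))
            pool = concat_frames(sessions)
            curve = scan_k(pool, 2, 10, n_replicates=3, seed=seed)
            hits += select_k_elbow(curve) == k_true
        assert hits >= 9

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4 k values"):
            select_k_elbow(KSelectionCurve([2, 3, 4], [1.0, 0.5, 0.4]))


class TestSilhouette:
    def test_tight_far_clusters(self, rng):
        a = np.concatenate([np.ones(8), -np.ones(8)])
        b = np.concatenate([-np.ones(8), np.ones(8)])
        frames = np.array([a] * 10 + [b] * 10) + rng.normal(0, 0.02, (20, 16))
        pool = _pool_from(frames)
        res = kmeans_caps(pool, 2, n_replicates=3, seed=0)
        sil = silhouette_by_cluster(pool, res)
        assert all(v > 0.9 for v in sil.values())

    def test_structureless_noise_near_zero(self, rng):
        pool = _pool_from(rng.normal(size=(60, 20)))
        res = kmeans_caps(pool, 3, n_replicates=3, seed=0)
        # random labels on the same structureless pool
        res.labels = rng.integers(1, 4, 60)
        sil = silhouette_by_cluster(pool, res)
        assert all(abs(v) < 0.15 for v in sil.values())


class TestLabelingAndSimilarity:
    def test_indicator_self_match_and_sign(self):
        table = default_parcel_table(70, 0)
        nets = table["network"].to_numpy()
        ind = (nets == "Vis").astype(float)
        lab = label_caps_by_network(np.vstack([ind, -ind]), table)
        assert lab.iloc[0]["Vis"] == pytest.approx(1.0)
        assert lab.iloc[1]["Vis"] == pytest.approx(-1.0)
        assert lab.iloc[0]["best_network"] == "Vis"

    def test_synthetic_states_label_to_generating_network(self, small_cohort, small_pool):
        _, _, _, truth = small_cohort
        res = kmeans_caps(small_pool, 6, n_replicates=4, seed=3)
        lab = label_caps_by_network(res, truth.parcel_table)
        # match fitted states to planted ones, then check each label
        ra, cb, r = match_clusters(res.centroids, truth.patterns.patterns)
        assert (r > 0.9).all()
        for i, j in zip(ra, cb):
            assert lab.iloc[i]["best_network"] == truth.patterns.networks[j]

    def test_centroid_similarity_properties(self, rng):
        pool = _pool_from(rng.normal(size=(30, 10)))
        res = kmeans_caps(pool, 3, n_replicates=3, seed=0)
        S = centroid_similarity_matrix(res)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(S), 1.0)
        brute = np.array(
            [[np.corrcoef(res.centroids[i], res.centroids[j])[0, 1] for j in range(3)] for i in range(3)]
        )
        np.fill_diagonal(brute, 1.0)
        np.testing.assert_allclose(S, brute, atol=1e-12)

    def test_frame_similarity_consistency(self, small_pool):
        res = kmeans_caps(small_pool, 6, n_replicates=2, seed=1)
        Xs = _standardize_rows(small_pool.frames)
        Cs = _standardize_rows(res.centroids, "centroid")
        R = Xs @ Cs.T / Xs.shape[1]
        own = R[np.arange(len(res.labels)), res.labels - 1]
        assert np.all(own >= R.max(axis=1) - 1e-10)
        agg = frame_centroid_similarity(small_pool, res)
        assert set(agg.columns) == {"subject_id", "group", "timepoint", "state", "r"}
        assert agg["r"].between(-1, 1).all()


class TestMatchClusters:
    def test_recovers_permutation(self, rng):
        C = rng.normal(size=(5, 30))
        perm = rng.permutation(5)
        ra, cb, r = match_clusters(C, C[perm])
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        np.testing.assert_array_equal(perm[cb], ra)

    def test_random_null_near_zero(self, rng):
        r = match_clusters(rng.normal(size=(4, 500)), rng.normal(size=(4, 500)))[2]
        assert np.abs(r).max() < 0.2

    def test_subgroup_vs_pooled_clustering(self, small_cohort, small_pool):
        """Clustering the depressed subgroup alone reproduces the pooled
        states (matched centroid correlations > 0.9)."""
        _, _, sessions, _ = small_cohort
        trd = [zscore_session(ts) for ts in sessions if ts.group == "TRD"]
        pool_trd = concat_frames(trd)
        res_all = kmeans_caps(small_pool, 6, n_replicates=4, seed=5)
        res_trd = kmeans_caps(pool_trd, 6, n_replicates=4, seed=5)
        _, _, r = match_clusters(res_trd.centroids, res_all.centroids)
        assert (r > 0.9).all()

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="ROI spaces"):
            match_clusters(rng.normal(size=(3, 10)), rng.normal(size=(3, 12)))


class TestAssignStates:
    def test_in_sample_equals_clustering_labels(self, small_cohort, small_pool):
        _, _, sessions, _ = small_cohort
        res = kmeans_caps(small_pool, 6, n_replicates=2, seed=2)
        zs = zscore_session(sessions[0])
        seq = assign_states(zs, res)
        np.testing.assert_array_equal(seq.labels, res.labels[: zs.n_frames])
        assert seq.run_boundaries.tolist() == zs.run_boundaries.tolist()

    def test_out_of_sample_nearest_centroid(self, rng):
        pool = _pool_from(rng.normal(size=(40, 12)))
        res = kmeans_caps(pool, 3, n_replicates=3, seed=0)
        data = np.vstack([res.centroids[2], res.centroids[0], res.centroids[1]])
        ts = RoiTimeSeries("new", "HC", "baseline", data, zscored=True)
        seq = assign_states(ts, res)
        assert seq.labels.tolist() == [3, 1, 2]

    def test_zero_noise_roundtrip(self):
        """Zero-noise sessions are perfectly recoverable: centroids match the
        planted patterns (r > 0.99) and the relabeled sequence is exact.
        Frames are clustered on the generator's own z scale (per-ROI
        re-standardization of noiseless block data distorts the patterns)."""
        import dataclasses

        table = default_parcel_table(70, 10)
        ps = make_state_patterns(6, table, seed=0)
        P = np.full((6, 6), 0.08)
        np.fill_diagonal(P, 0.6)
        mk = MarkovParams(np.full(6, 1 / 6), P)
        ts, true_seq = simulate_session(ps, mk, 150, n_runs=2, noise_sigma=0.0, seed=1)
        zs = dataclasses.replace(ts, zscored=True)  # patterns already on z scale
        pool = concat_frames([zs])
        res = kmeans_caps(pool, 6, n_replicates=5, seed=1)
        ra, cb, r = match_clusters(res.centroids, ps.patterns)
        assert (r > 0.99).all()
        relabel = {int(a) + 1: int(b) + 1 for a, b in zip(ra, cb)}
        seq = assign_states(zs, res)
        np.testing.assert_array_equal(
            np.array([relabel[s] for s in seq.labels]), true_seq.labels
        )

    def test_roi_mismatch(self, rng):
        pool = _pool_from(rng.normal(size=(20, 10)))
        res = kmeans_caps(pool, 2, n_replicates=2, seed=0)
        ts = RoiTimeSeries("x", "HC", "baseline", rng.normal(size=(5, 11)), zscored=True)
        with pytest.raises(ValueError, match="ROI space"):
            assign_states(ts, res)


class TestFramePool:
    def test_counting_and_roundtrip(self, rng):
        def mk(sub, frames):
            return RoiTimeSeries(sub, "HC", "baseline", rng.normal(size=(frames, 4)), zscored=True)

        pool = concat_frames([mk("a", 5), mk("b", 7)])
        assert pool.n_frames == 12 and len(pool.index_map) == 12
        seqs = pool.split_labels(np.arange(12) % 3 + 1)
        assert [len(s) for s in seqs] == [5, 7]
        np.testing.assert_array_equal(seqs[0].labels, (np.arange(5) % 3) + 1)

    def test_empty_and_mixed_errors(self, rng):
        with pytest.raises(ValueError, match="no sessions"):
            concat_frames([])
        a = RoiTimeSeries("a", "HC", "baseline", rng.normal(size=(5, 4)), zscored=True)
        b = RoiTimeSeries("b", "HC", "baseline", rng.normal(size=(5, 5)), zscored=True)
        with pytest.raises(ValueError, match="mixed parcel"):
            concat_frames([a, b])
        c = RoiTimeSeries("c", "HC", "baseline", rng.normal(size=(5, 4)), zscored=False)
        with pytest.raises(ValueError, match="not z-scored"):
            concat_frames([c])
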