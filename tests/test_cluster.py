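import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from voxelus import cluster as vc
from voxelus import synth
from voxelus.core import RegionLabelMap
from voxelus.errors import ComparabilityError, LookupError_, ParameterError

from conftest import make_trialset


def blobs(n_per=40, k=5, dim=12, sep=30.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, dim))
    pts = np.vstack([c + rng.normal(size=(n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


@pytest.fixture(scope="module")
def clustered_synth():
    """Noisy dataset with 4 planted response classes + background in SCs."""
    cfg = synth.SynthConfig(grid_shape=(24, 24), n_trials=20,
                            conditions=(100.0,), frame_noise_sd_percent=3.0,
                            active_fraction_scs=0.7, rng_seed=13)
    ts, gt = synth.generate(cfg)
    matrix, index = vc.build_feature_matrix([ts], gt.labelmap, "SCs")
    return cfg, ts, gt, matrix, index


class TestBuildFeatureMatrix:
    def test_row_count_subjects_by_conditions(self):
        cfg = synth.SynthConfig(grid_shape=(10, 10), n_trials=2,
                                conditions=(10.0, 50.0, 100.0),
                                frame_noise_sd_percent=1.0, rng_seed=1)
        ts_a, gt = synth.generate(cfg)
        ts_b, _ = synth.generate(
            synth.SynthConfig(**{**cfg.__dict__, "rng_seed": 2,
                                 "subject_id": "m2"}))
        n_scs = (gt.labelmap.labels == 1).sum()
        matrix, index = vc.build_feature_matrix([ts_a, ts_b], gt.labelmap, "SCs")
        assert len(index.entries) == 2 * 3 * n_scs
        # with noise, duplicates are essentially impossible
        assert matrix.shape == (2 * 3 * n_scs, ts_a.n_frames)
        np.testing.assert_array_equal(index.back_index,
                                      np.arange(2 * 3 * n_scs))

    def test_duplicates_removed_back_index_covers_all(self, noiseless_data):
        # noiseless traces repeat across voxels of the same planted class
        ts, gt = noiseless_data
        matrix, index = vc.build_feature_matrix([ts], gt.labelmap, "SCs")
        assert matrix.shape[0] < len(index.entries)
        assert index.back_index.shape == (len(index.entries),)
        assert len(np.unique(matrix, axis=0)) == matrix.shape[0]

    def test_deterministic_row_order(self, clustered_synth):
        _, ts, gt, matrix, index = clustered_synth
        matrix2, index2 = vc.build_feature_matrix([ts], gt.labelmap, "SCs")
        np.testing.assert_array_equal(matrix, matrix2)
        assert index.entries == index2.entries


class TestFitPca:
    def test_rank_one_single_component(self):
        rng = np.random.default_rng(0)
        matrix = np.outer(rng.normal(size=30), rng.normal(size=10))
        feats, pca = vc.fit_pca(matrix, variance_target=0.5)
        assert pca.n_components_ == 1
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_full_variance_needs_rank_components(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(size=(20, 6))
        feats, pca = vc.fit_pca(matrix, variance_target=1.0)
        assert pca.n_components_ == 6  # full-rank centered data

    def test_cumulative_curve_monotone_to_one(self):
        rng = np.random.default_rng(2)
        matrix = rng.normal(size=(30, 8))
        _, pca = vc.fit_pca(matrix, variance_target=1.0)
        cum = np.cumsum(pca.explained_variance_ratio_)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0)

    def test_bad_target_rejected(self):
        with pytest.raises(ParameterError):
            vc.fit_pca(np.ones((5, 3)), variance_target=1.5)

    def test_target_threshold_selection(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(size=(50, 10)) * np.array([10, 5, 3] + [1] * 7)
        _, probe = vc.fit_pca(matrix, variance_target=1.0)
        cum = np.cumsum(probe.explained_variance_ratio_)
        for target in (0.3, 0.5, 0.8):
            _, pca = vc.fit_pca(matrix, variance_target=target)
            m = pca.n_components_
            assert cum[m - 1] >= target
            if m > 1:
                assert cum[m - 2] < target


class TestElbow:
    def test_five_blobs_suggest_five(self):
        pts, _ = blobs(k=5, seed=4)
        _, k = vc.elbow_k(pts, range(2, 11), seed=0)
        assert k == 5

    def test_inertia_nonincreasing(self):
        pts, _ = blobs(k=3, seed=5)
        inertias, _ = vc.elbow_k(pts, range(1, 9), seed=0)
        assert np.all(np.diff(inertias) <= 1e-6)

    def test_degenerate_curve_flagged(self):
        pts = np.ones((10, 4))
        inertias, k = vc.elbow_k(pts, [1], seed=0)
        assert inertias[0] == pytest.approx(0.0)
        assert k is None


def _fitted(matrix, ts, k=5, seed=0, n_init=20, variance_target=0.9):
    feats, pca = vc.fit_pca(matrix, variance_target=variance_target)
    model = vc.fit_kmeans(feats, pca, ts, k, n_init=n_init, seed=seed)
    return feats, pca, model


class TestFitKmeans:
    def test_k1_inertia_total_scatter(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        feats, pca, model = _fitted(matrix, ts, k=1)
        expected = ((feats - feats.mean(axis=0)) ** 2).sum()
        assert model.inertia == pytest.approx(expected, rel=1e-9)

    def test_planted_blobs_perfect_ari(self, timing_ts):
        pts, truth = blobs(k=3, seed=6)
        km = KMeans(n_clusters=3, n_init=10, algorithm="elkan", random_state=0).fit(pts)
        assert adjusted_rand_score(truth, km.labels_) == 1.0

    def test_inertia_self_consistent(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        feats, pca, model = _fitted(matrix, ts, k=5)
        recomputed = sum(
            ((feats[model.labels == cid] - model.centroids[cid - 1]) ** 2).sum()
            for cid in range(1, 6))
        assert recomputed == pytest.approx(model.inertia, abs=1e-9 * max(1, model.inertia))

    def test_amplitude_ordering(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        _, _, model = _fitted(matrix, ts, k=5)
        traces = model.centroid_traces()
        onset, offset = ts.stimulus_onset_frame, ts.stimulus_offset_frame
        peaks = traces[:, onset:offset].max(axis=1)
        assert np.all(np.diff(peaks) >= 0)

    def test_k_exceeding_samples_rejected(self, timing_ts):
        with pytest.raises(ParameterError):
            feats, pca = vc.fit_pca(np.random.default_rng(0).normal(size=(4, 6)),
                                    variance_target=1.0)
            vc.fit_kmeans(feats, pca, timing_ts, 10)

    def test_best_of_inits_monotone(self, clustered_synth):
        # min over a nested set of single-init runs can only improve
        _, ts, _, matrix, _ = clustered_synth
        feats, pca = vc.fit_pca(matrix, variance_target=0.9)
        inertias = [KMeans(n_clusters=5, n_init=1, algorithm="elkan",
                           random_state=s).fit(feats).inertia_ for s in range(10)]
        assert min(inertias[:10]) <= min(inertias[:3])


class TestClusterTraces:
    def test_identical_members_zero_sd(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        rows = np.tile(np.sin(np.linspace(0, 2, matrix.shape[1])), (6, 1))
        feats, pca = vc.fit_pca(rows + np.random.default_rng(0).normal(
            scale=1e-12, size=rows.shape), n_components=2)
        model = vc.fit_kmeans(feats, pca, ts, 1, n_init=2, seed=0)
        traces = vc.cluster_traces(model, rows)
        mean, sd = traces[1]
        np.testing.assert_allclose(sd, 0.0, atol=1e-9)

    def test_size_weighted_mean_decomposition(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        _, _, model = _fitted(matrix, ts, k=4)
        traces = vc.cluster_traces(model, matrix)
        acc = np.zeros(matrix.shape[1])
        for cid, (mean, _) in traces.items():
            acc += mean * (model.labels == cid).sum()
        np.testing.assert_allclose(acc / len(matrix), matrix.mean(axis=0),
                                   atol=1e-9)

    def test_member_peaks_nondecreasing_in_id(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        _, _, model = _fitted(matrix, ts, k=5)
        traces = vc.cluster_traces(model, matrix)
        onset, offset = ts.stimulus_onset_frame, ts.stimulus_offset_frame
        peaks = [traces[cid][0][onset:offset].max() for cid in range(1, 6)]
        assert np.all(np.diff(peaks) >= -0.5)  # noise tolerance


class TestClusterMap:
    def test_partition_and_determinism(self, clustered_synth):
        _, ts, gt, matrix, index = clustered_synth
        _, _, model = _fitted(matrix, ts, k=5)
        m1 = vc.cluster_map(model, index, ts.subject_id, 100.0)
        m2 = vc.cluster_map(model, index, ts.subject_id, 100.0)
        np.testing.assert_array_equal(m1.ids, m2.ids)
        analyzed = m1.ids > 0
        assert analyzed.sum() == (gt.labelmap.labels == 1).sum()
        assert set(np.unique(m1.ids[analyzed])) <= set(range(1, 6))

    def test_duplicates_inherit_representative_label(self, noiseless_data):
        ts, gt = noiseless_data
        matrix, index = vc.build_feature_matrix([ts], gt.labelmap, "SCs")
        feats, pca = vc.fit_pca(matrix, n_components=min(3, matrix.shape[0] - 1))
        model = vc.fit_kmeans(feats, pca, ts, min(3, len(matrix)), n_init=5, seed=0)
        full = model.full_labels(index)
        # all voxels of one planted class share one trace -> one label
        for i, (subj, cond, z, x) in enumerate(index.entries):
            rep = index.back_index[i]
            assert full[i] == model.labels[rep]

    def test_unknown_subject_rejected(self, clustered_synth):
        _, ts, _, matrix, index = clustered_synth
        _, _, model = _fitted(matrix, ts, k=2)
        with pytest.raises(LookupError_):
            vc.cluster_map(model, index, "nope", 100.0)


class TestMapSimilarity:
    def _map(self, ids, k=5):
        return vc.ClusterMap(ids=np.asarray(ids, dtype=np.int32),
                             subject="s", condition=100.0, k=k)

    def test_identical_maps(self):
        ids = np.array([[1, 2], [3, 0]])
        assert vc.map_similarity(self._map(ids), self._map(ids)) == 1.0

    def test_everywhere_different(self):
        a = np.array([[1, 2], [3, 0]])
        b = np.array([[2, 3], [1, 0]])
        assert vc.map_similarity(self._map(a), self._map(b)) == 0.0

    def test_partial_agreement(self):
        a = np.zeros((10, 10), dtype=np.int32) + 1
        b = a.copy()
        b.flat[:5] = 2
        assert vc.map_similarity(self._map(a), self._map(b)) == pytest.approx(0.95)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 6, (8, 8))
        b = rng.integers(1, 6, (8, 8))
        assert (vc.map_similarity(self._map(a), self._map(b))
                == vc.map_similarity(self._map(b), self._map(a)))

    def test_mismatched_analyzed_sets_rejected(self):
        a = np.array([[1, 0]])
        b = np.array([[1, 2]])
        with pytest.raises(ComparabilityError):
            vc.map_similarity(self._map(a), self._map(b))


class TestStability:
    def test_two_runs_single_pair(self, clustered_synth):
        _, ts, _, matrix, index = clustered_synth
        feats, pca = vc.fit_pca(matrix, variance_target=0.9)
        mean, sd = vc.stability(feats, pca, ts, 3, index=index, n_runs=2,
                                n_init=5, seed=0)
        assert 0.0 <= mean <= 1.0
        assert sd == 0.0  # one pair -> zero spread

    def test_separable_data_perfectly_stable(self, clustered_synth):
        _, ts, _, matrix, _ = clustered_synth
        feats, pca = vc.fit_pca(matrix, variance_target=0.9)
        mean, sd = vc.stability(feats, pca, ts, 5, n_runs=4, n_init=20, seed=1)
        assert mean == 1.0 and sd == 0.0


class TestRegionDistribution:
    def test_matches_bruteforce_toy_map(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[:2] = 1
        labels[2:4] = 2
        labels[4:] = 3
        lm = RegionLabelMap(labels=labels, lookup={1: "SCs", 2: "SCi", 3: "SCd"})
        rng = np.random.default_rng(9)
        ids = rng.integers(0, 4, (6, 6)).astype(np.int32)
        cmap = vc.ClusterMap(ids=ids, subject="s", condition=100.0, k=3)
        per_cluster, per_region = vc.cluster_region_distribution([cmap], lm)
        for cid in range(1, 4):
            total = (ids == cid).sum()
            for lbl, acr in lm.lookup.items():
                expected = 100.0 * ((ids == cid) & (labels == lbl)).sum() / total
                assert per_cluster[cid][acr] == pytest.approx(expected)

    def test_rows_sum_to_hundred(self, clustered_synth):
        _, ts, gt, matrix, index = clustered_synth
        _, _, model = _fitted(matrix, ts, k=5)
        cmap = vc.cluster_map(model, index, ts.subject_id, 100.0)
        per_cluster, per_region = vc.cluster_region_distribution([cmap], gt.labelmap)
        for cid, dist in per_cluster.items():
            vals = list(dist.values())
            if not np.isnan(vals).any():
                assert sum(vals) == pytest.approx(100.0, abs=1e-9)
        for acr, by_cond in per_region.items():
            for cond, dist in by_cond.items():
                assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_region_cluster(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        lm = RegionLabelMap(labels=labels, lookup={1: "SCs", 2: "SCi"})
        ids = np.zeros((4, 4), dtype=np.int32)
        ids[0, :] = 1  # cluster 1 entirely inside SCs
        cmap = vc.ClusterMap(ids=ids, subject="s", condition=10.0, k=1)
        per_cluster, _ = vc.cluster_region_distribution([cmap], lm)
        assert per_cluster[1]["SCs"] == 100.0
        assert per_cluster[1]["SCi"] == 0.0


class TestPipelineRecovery:
    def test_planted_classes_recovered(self, clustered_synth):
        cfg, ts, gt, matrix, index = clustered_synth
        feats, pca = vc.fit_pca(matrix, variance_target=0.5)
        model = vc.fit_kmeans(feats, pca, ts, 5, n_init=50, seed=0)
        full = model.full_labels(index)
        truth = np.array([gt.class_map[z, x] for (_, _, z, x) in index.entries])
        assert adjusted_rand_score(truth, full) >= 0.9
        # amplitude ordering: planted class i (ascending amplitude) should map
        # to the i+1-th cluster id
        for ci in range(5):
            ids_here = full[truth == ci]
            majority = np.bincount(ids_here).argmax()
            assert majority == ci + 1
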