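import warnings

import numpy as np
import pandas as pd
import pytest

from habitatvpi.habitat import (
    ClusterModel,
    assign_habitats,
    davies_bouldin,
    fit_habitat_model,
    impute_missing_habitats,
    missing_habitats,
    pca_projection,
    select_k,
    slic3d,
    superpixel_features,
)
from habitatvpi.preprocess import CTVolume


def naive_davies_bouldin(x, labels):
    """Independent literal implementation of the DB definition."""
    uniq = sorted(set(labels))
    cents = {u: x[labels == u].mean(0) for u in uniq}
    s = {
        u: np.mean([np.linalg.norm(p - cents[u]) for p in x[labels == u]])
        for u in uniq
    }
    total = 0.0
    for i in uniq:
        total += max(
            (s[i] + s[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in uniq if j != i
        )
    return total / len(uniq)


class TestSlic:
    def test_uniform_cube_partition_properties(self):
        vol = CTVolume(np.zeros((20, 20, 20)))
        mask = np.ones((20, 20, 20), dtype=bool)
        sp = slic3d(vol, mask, n_superpixels=50)
        assert 1 <= sp.n_superpixels <= 50
        # labels partition the mask
        assert (sp.labels[mask] > 0).all()
        assert (sp.labels[~mask] == 0).all()
        sizes = np.bincount(sp.labels[mask])[1:]
        assert sizes.min() > 0
        assert sizes.max() / sizes.min() < 4  # near-equal sizes on uniform input

    def test_tiny_mask_one_superpixel_per_voxel(self):
        vol = CTVolume(np.zeros((5, 5, 5)))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, :2] = True
        mask[2, :4, 2] = True
        with pytest.warns(UserWarning):
            sp = slic3d(vol, mask, n_superpixels=50)
        assert sp.n_superpixels == int(mask.sum())

    def test_low_compactness_follows_intensity_boundary(self):
        # a two-intensity split cube: intensity-driven (low compactness)
        # superpixels should straddle the boundary less often
        rng = np.random.default_rng(0)
        data = np.where(np.arange(24)[:, None, None] < 12, -1.0, 1.0)
        data = data + rng.normal(0, 0.05, size=(24, 24, 24))
        vol = CTVolume(data)
        mask = np.ones((24, 24, 24), dtype=bool)
        truth = np.broadcast_to(np.arange(24)[:, None, None] < 12, mask.shape)

        def straddlers(compactness):
            sp = slic3d(vol, mask, n_superpixels=50, compactness=compactness)
            n = 0
            for s in range(1, sp.n_superpixels + 1):
                frac = truth[sp.labels == s].mean()
                n += 0.0 < frac < 1.0
            return n / sp.n_superpixels

        assert straddlers(0.1) < straddlers(10.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            slic3d(CTVolume(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))


class TestSuperpixelFeatures:
    def test_hand_computed_stats(self):
        vol = CTVolume(np.array([[[1.0, 2.0, 3.0, 4.0]]]))
        labels = np.array([[[1, 1, 1, 1]]], dtype=np.int32)
        from habitatvpi.habitat import SuperpixelMap

        f = superpixel_features(vol, SuperpixelMap(labels, np.array([0, 4])))
        assert f.loc[1, "mean"] == 2.5
        assert f.loc[1, "median"] == 2.5
        assert f.loc[1, "variance"] == 1.25  # population convention
        assert f.loc[1, "skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_superpixel_conventions(self):
        vol = CTVolume(np.full((1, 1, 3), 2.0))
        labels = np.array([[[1, 1, 1]]], dtype=np.int32)
        from habitatvpi.habitat import SuperpixelMap

        f = superpixel_features(vol, SuperpixelMap(labels, np.array([0, 3])))
        row = f.loc[1]
        assert row["variance"] == 0
        assert row["skewness"] == 0 and row["kurtosis"] == 0
        assert row["minimum"] == row["maximum"] == row["mean"]


class TestClustering:
    @staticmethod
    def _blobs(seed=0, n=150, k=3, sep=8.0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, sep, size=(k, 10))
        x = np.vstack([c + rng.normal(0, 1, size=(n // k, 10)) for c in centers])
        truth = np.repeat(np.arange(k), n // k)
        return pd.DataFrame(x, columns=[f"f{i}" for i in range(10)]), truth

    def test_recovers_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        feats, truth = self._blobs()
        model = fit_habitat_model(feats, k=3, seed=0)
        got = model.predict(feats)
        assert adjusted_rand_score(truth, got) > 0.95

    def test_k1_single_habitat(self):
        feats, _ = self._blobs()
        model = fit_habitat_model(feats, k=1, seed=0)
        assert set(model.predict(feats)) == {1}

    def test_deterministic_under_seed(self):
        feats, _ = self._blobs()
        m1 = fit_habitat_model(feats, k=3, seed=5)
        m2 = fit_habitat_model(feats, k=3, seed=5)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_too_many_clusters_raises(self):
        feats, _ = self._blobs(n=6)
        with pytest.raises(ValueError):
            fit_habitat_model(feats.iloc[:2], k=5)

    def test_select_k_finds_two_blobs(self):
        feats, _ = self._blobs(k=2, n=200, sep=10.0)
        best, curve = select_k(feats, range(2, 7), seed=0)
        assert best == 2
        assert set(curve) == {2, 3, 4, 5, 6}

    def test_argmin_semantics_on_published_curve(self):
        # the published DB values for K=2..10 have their minimum at K=4
        # (even though that study fixed K=3); the selection rule is a pure
        # argmin with ties to the smaller K
        published = dict(zip(range(2, 11),
                             [1.038, 0.991, 0.977, 1.083, 1.093, 1.087,
                              1.127, 1.114, 1.092]))
        assert min(published, key=lambda k: (published[k], k)) == 4

    def test_select_k_tie_breaks_low(self):
        # argmin semantics on the recorded curve: equal minima -> smallest K
        curve = {2: 1.0, 3: 0.9, 4: 0.9, 5: 1.1}
        assert min(curve, key=lambda k: (curve[k], k)) == 3

    def test_structureless_data_scores_worse_than_true_clusters(self):
        # a single Gaussian cloud has no K at which the DB index approaches
        # the score of genuinely separated blobs
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(300, 10)))
        _, noise_curve = select_k(x, range(2, 8), seed=0)
        blobs, _ = self._blobs(k=3, n=300, sep=8.0)
        _, blob_curve = select_k(blobs, range(2, 8), seed=0)
        assert min(noise_curve.values()) > 3 * min(blob_curve.values())


class TestDaviesBouldin:
    def test_closed_form_two_clusters(self):
        # two 1-D clusters with within-scatter 1 each, centroids 10 apart
        x = np.array([[-1.0], [1.0], [9.0], [11.0]])
        lab = np.array([0, 0, 1, 1])
        assert davies_bouldin(x, lab) == pytest.approx(0.2)

    def test_matches_naive_definition_and_sklearn(self):
        from sklearn.metrics import davies_bouldin_score

        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 4))
        lab = rng.integers(0, 3, size=50)
        got = davies_bouldin(x, lab)
        assert got == pytest.approx(naive_davies_bouldin(x, lab))
        assert got == pytest.approx(davies_bouldin_score(x, lab))

    def test_duplicate_centroids_guarded(self):
        x = np.array([[0.0], [0.0], [0.0], [0.0]])
        with pytest.raises(ValueError):
            davies_bouldin(x, np.array([0, 0, 1, 1]))


class TestAssignment:
    def test_training_lesion_reproduces_fit_labels(self, preprocessed_cohort,
                                                   fitted_habitats):
        spmaps, model, maps = fitted_habitats
        cid = sorted(preprocessed_cohort)[0]
        norm = preprocessed_cohort[cid][2]
        again = assign_habitats(norm, spmaps[cid], model)
        np.testing.assert_array_equal(maps[cid], again)

    def test_habitat_maps_partition_lesions(self, preprocessed_cohort,
                                            fitted_habitats):
        _, model, maps = fitted_habitats
        for cid, hmap in list(maps.items())[:10]:
            lesion = preprocessed_cohort[cid][1]
            assert ((hmap > 0) == lesion).all()
            assert set(np.unique(hmap)) <= {0, 1, 2, 3}

    def test_subregion_truth_recovery(self, small_cohort, preprocessed_cohort,
                                      fitted_habitats):
        from sklearn.metrics import adjusted_rand_score

        _, model, maps = fitted_habitats
        aris = []
        for case in small_cohort:
            lesion = preprocessed_cohort[case.case_id][1]
            sub = preprocessed_cohort[case.case_id][4]
            aris.append(adjusted_rand_score(sub[lesion],
                                            maps[case.case_id][lesion]))
        assert np.mean(aris) > 0.6

    def test_serialization_round_trip(self, tmp_path, preprocessed_cohort,
                                      fitted_habitats):
        spmaps, model, maps = fitted_habitats
        model.to_json(tmp_path / "cm.json")
        loaded = ClusterModel.from_json(tmp_path / "cm.json")
        cid = sorted(preprocessed_cohort)[1]
        norm = preprocessed_cohort[cid][2]
        np.testing.assert_array_equal(
            assign_habitats(norm, spmaps[cid], loaded), maps[cid]
        )

    def test_missing_habitat_reporting(self):
        hmap = np.zeros((4, 4, 4), dtype=int)
        hmap[1:3, 1:3, 1:3] = 2
        assert missing_habitats(hmap, 3) == [1, 3]


class TestImputation:
    @staticmethod
    def _blocked_table(seed=0, n=82, n_missing=7):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=(n, 3))
        cols = {}
        for h in (1, 2, 3):
            for j in range(6):
                w = rng.normal(size=3)
                cols[f"Habitat{h}_f{j}"] = latent @ w + rng.normal(0, 0.3, n)
        full = pd.DataFrame(cols)
        masked = full.copy()
        rows = rng.choice(n, size=n_missing, replace=False)
        block = [c for c in full.columns if c.startswith("Habitat2_")]
        masked.loc[masked.index[rows], block] = np.nan
        return full, masked, rows, block

    def test_no_missing_is_identity(self):
        full, *_ = self._blocked_table()
        out = impute_missing_habitats(full, seed=0)
        pd.testing.assert_frame_equal(out, full)

    def test_beats_mean_imputation(self):
        full, masked, rows, block = self._blocked_table(seed=1)
        out = impute_missing_habitats(masked, seed=0)
        truth = full.iloc[rows][block].to_numpy()
        rf_rmse = np.sqrt(((out.iloc[rows][block].to_numpy() - truth) ** 2).mean())
        mean_fill = masked.fillna(masked.mean())
        mean_rmse = np.sqrt(
            ((mean_fill.iloc[rows][block].to_numpy() - truth) ** 2).mean()
        )
        assert rf_rmse < mean_rmse

    def test_fully_missing_feature_raises(self):
        _, masked, *_ = self._blocked_table()
        masked["Habitat1_f0"] = np.nan
        with pytest.raises(ValueError):
            impute_missing_habitats(masked, seed=0)

    def test_imputed_block_count_matches_injection(self, fitted_habitats):
        # injected whole-block missingness is reported exactly
        _, masked, rows, block = self._blocked_table(seed=2, n=60, n_missing=9)
        miss_blocks = int(masked[block].isna().all(axis=1).sum())
        assert miss_blocks == 9
        out = impute_missing_habitats(masked, seed=1)
        assert out.isna().sum().sum() == 0


class TestPCA:
    def test_line_explains_everything(self):
        t = np.linspace(0, 1, 30)
        x = np.column_stack([t, 2 * t, -t])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, ev = pca_projection(x + 1e-9)
        assert ev[0] > 0.999

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        _, ev1 = pca_projection(x, standardize=False)
        _, ev2 = pca_projection(x @ q, standardize=False)
        np.testing.assert_allclose(ev1, ev2, atol=1e-8)

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 4))
        z = (x - x.mean(0)) / x.std(0)
        coords, ev = pca_projection(x)
        w = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        np.testing.assert_allclose(ev[:2], w[:2] / w.sum(), rtol=1e-8)
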