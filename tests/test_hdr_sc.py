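import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from glycoscape import hdr_sc
from glycoscape import msi_io
from glycoscape import phantom as ph
from glycoscape import preprocess as pp
from conftest import make_fm


class TestClusterPixels:
    def test_noiseless_regions_exact(self, noiseless_fm):
        fm, truth = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        tl = truth.labels_for(fm.coords)
        assert adjusted_rand_score(tl, cr.labels) == 1.0
        assert cr.n_clusters == len(np.unique(tl))

    def test_noisy_ari(self, panel):
        aris = []
        for seed in range(5):
            cfg = ph.default_config(noise_cv=0.2, seed=seed, grid=(40, 40),
                                    panel=panel)
            ds, truth = ph.make_phantom(cfg, panel)
            fm = pp.tic_normalize(pp.integrate_panel(ds, panel))
            cr = hdr_sc.cluster_pixels(fm, seed=seed)
            aris.append(
                adjusted_rand_score(truth.labels_for(fm.coords), cr.labels)
            )
        assert np.mean(aris) >= 0.9

    def test_identical_pixels_single_cluster(self, panel):
        fm = make_fm(np.ones((30, 5)), panel)
        cr = hdr_sc.cluster_pixels(fm, k_neighbors=5)
        assert cr.n_clusters == 1

    def test_k_too_large_rejected(self, panel):
        fm = make_fm(np.random.default_rng(0).random((10, 4)), panel)
        with pytest.raises(ValueError, match="k_neighbors"):
            hdr_sc.cluster_pixels(fm, k_neighbors=10)

    def test_requires_normalized(self, panel):
        fm = make_fm(np.ones((10, 4)), panel, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            hdr_sc.cluster_pixels(fm)

    def test_determinism(self, noiseless_fm):
        fm, _ = noiseless_fm
        a = hdr_sc.cluster_pixels(fm, seed=5)
        b = hdr_sc.cluster_pixels(fm, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_dense_by_size(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        _, counts = np.unique(cr.labels, return_counts=True)
        assert sorted(np.unique(cr.labels)) == list(range(cr.n_clusters))
        assert list(counts) == sorted(counts, reverse=True)

    def test_pixel_order_invariance(self, noiseless_fm, panel):
        import pandas as pd

        fm, _ = noiseless_fm
        perm = np.random.default_rng(3).permutation(fm.n_pixels)
        fm_p = pp.FeatureMatrix(
            values=fm.values.iloc[perm].reset_index(drop=True),
            tic=fm.tic[perm],
            frame=fm.frame.iloc[perm].reset_index(drop=True),
            panel=panel,
            normalized=True,
        )
        a = hdr_sc.cluster_pixels(fm, seed=0).labels
        b = hdr_sc.cluster_pixels(fm_p, seed=0).labels
        # compare as partitions on the same pixels
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert adjusted_rand_score(a, b[inv]) == 1.0


class TestEmbed2d:
    def test_determinism_and_separation(self, panel):
        cfg = ph.default_config(noise_cv=0.1, seed=2, grid=(20, 20),
                                panel=panel)
        ds, truth = ph.make_phantom(cfg, panel)
        fm = pp.tic_normalize(pp.integrate_panel(ds, panel))
        e1 = hdr_sc.embed_2d(fm, seed=7)
        e2 = hdr_sc.embed_2d(fm, seed=7)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (fm.n_pixels, 2)
        tl = truth.labels_for(fm.coords)
        on = tl != ph.MATRIX_REGION_ID
        assert silhouette_score(e1[on], tl[on]) > 0.5

    def test_too_few_pixels(self, panel):
        fm = make_fm(np.random.default_rng(0).random((3, 4)), panel)
        with pytest.raises(ValueError, match="4 pixels"):
            hdr_sc.embed_2d(fm)


class TestMatrixFlagging:
    def test_phantom_border_flagged(self, noiseless_fm):
        fm, truth = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        flagged = hdr_sc.flag_matrix_clusters(cr, fm)
        tl = truth.labels_for(fm.coords)
        matrix_clusters = set(
            np.unique(cr.labels[tl == ph.MATRIX_REGION_ID]).tolist()
        )
        tissue_clusters = set(
            np.unique(cr.labels[tl != ph.MATRIX_REGION_ID]).tolist()
        )
        assert set(flagged) == matrix_clusters
        assert not (set(flagged) & tissue_clusters)

    def test_threshold_one_flags_nothing(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        # strictly above 1.0 is impossible for a fraction
        assert hdr_sc.flag_matrix_clusters(cr, fm, 1.0 + 1e-9) == frozenset()

    def test_monotone_in_threshold(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            cur = hdr_sc.flag_matrix_clusters(cr, fm, thr)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_panel_without_matrix_rejected(self):
        from glycoscape import carbo_masses as cm

        p = cm.build_default_panel(matrix_mz_list=[779.1646])
        p2 = cm.PeakPanel(
            tuple(e for e in p.entries if e.feature_class != "matrix")
        )
        fm = make_fm(np.ones((10, len(p2))), p2)
        cr = hdr_sc.cluster_pixels(fm, k_neighbors=3)
        with pytest.raises(ValueError, match="matrix"):
            hdr_sc.flag_matrix_clusters(cr, fm)


class TestRemoveAndFinalize:
    def test_retained_matches_truth(self, noiseless_fm):
        fm, truth = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        cr.matrix_cluster_ids = hdr_sc.flag_matrix_clusters(cr, fm)
        out = hdr_sc.remove_and_finalize(cr, fm)
        tl = truth.labels_for(fm.coords)
        kept = np.zeros(fm.n_pixels, bool)
        kept[out.retained] = True
        tissue = tl != ph.MATRIX_REGION_ID
        precision = (kept & tissue).sum() / kept.sum()
        recall = (kept & tissue).sum() / tissue.sum()
        assert precision >= 0.99 and recall >= 0.99

    def test_noop_keep_labels_is_identity(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        out = hdr_sc.remove_and_finalize(cr, fm, mode="keep_labels")
        np.testing.assert_array_equal(out.labels, cr.labels)
        np.testing.assert_array_equal(out.retained, cr.retained)

    def test_recluster_determinism(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        cr.matrix_cluster_ids = hdr_sc.flag_matrix_clusters(cr, fm)
        a = hdr_sc.remove_and_finalize(cr, fm, mode="recluster")
        b = hdr_sc.remove_and_finalize(cr, fm, mode="recluster")
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_removing_everything_rejected(self, noiseless_fm):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        cr.matrix_cluster_ids = frozenset(np.unique(cr.labels).tolist())
        with pytest.raises(ValueError, match="every pixel"):
            hdr_sc.remove_and_finalize(cr, fm)


class TestSpatialMap:
    def test_map_equals_truth_up_to_permutation(self, noiseless_fm, tmp_path):
        fm, truth = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        csv = hdr_sc.spatial_map(cr, fm, tmp_path / "map")
        df = msi_io.read_label_map_csv(csv)
        tl = truth.label_map[df["y"], df["x"]]
        assert adjusted_rand_score(tl, df["value"]) == 1.0

    def test_removed_pixels_absent(self, noiseless_fm, tmp_path):
        fm, truth = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        cr.matrix_cluster_ids = hdr_sc.flag_matrix_clusters(cr, fm)
        out = hdr_sc.remove_and_finalize(cr, fm)
        csv = hdr_sc.spatial_map(out, fm, tmp_path / "map2")
        df = msi_io.read_label_map_csv(csv)
        tl = truth.label_map[df["y"], df["x"]]
        assert (tl == ph.MATRIX_REGION_ID).mean() < 0.01

    def test_frame_mismatch_rejected(self, noiseless_fm, panel, tmp_path):
        fm, _ = noiseless_fm
        cr = hdr_sc.cluster_pixels(fm, seed=0)
        small = make_fm(np.ones((4, 4)), panel)
        with pytest.raises(ValueError, match="frame"):
            hdr_sc.spatial_map(cr, small, tmp_path / "bad")
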