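import io

import numpy as np
import pytest

from phenofuse.analysis import (
    ClusterTree, build_cluster_tree, class_mean_features, grad_cam,
    heat_inside_fraction, tsne_embed,
)
from phenofuse.backbones import FeatureMatrix, TrainConfig, build_backbone, finetune
from phenofuse.errors import ConfigError, DataError
from phenofuse.segmentation import segment_scan
from phenofuse.synthetic import render_scan


@pytest.fixture(scope="module")
def tiny():
    return build_backbone("tiny", 5, rng_seed=0)


class TestGradCam:
    def test_heatmap_has_layer_spatial_resolution(self, tiny):
        model, spec = tiny
        img = np.random.default_rng(0).integers(0, 255, (300, 300, 3), dtype=np.uint8)
        cam = grad_cam(model, spec, img, "conv3_relu", target_class=2)
        assert cam.heatmap.shape == (16, 16)           # conv3 at 64 input
        assert cam.overlay.shape == (64, 64)
        assert cam.heatmap.min() >= 0 and cam.heatmap.max() <= 1

    def test_zero_weight_head_gives_zero_map(self):
        model, spec = build_backbone("tiny", 4, rng_seed=1)
        head = next(n.layer for n in model.nodes if n.name == "fc")
        head.params["W"][:] = 0
        head.params["b"][:] = 0
        img = np.random.default_rng(1).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        cam = grad_cam(model, spec, img, "conv3_relu", target_class=0)
        assert np.all(cam.heatmap == 0)

    def test_single_positive_channel_recovers_that_activation(self):
        model, spec = build_backbone("tiny", 4, rng_seed=2)
        head = next(n.layer for n in model.nodes if n.name == "fc")
        head.params["W"][:] = 0
        head.params["W"][7, 1] = 1.0                   # class 1 <- channel 7 only
        img = np.random.default_rng(2).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        cam = grad_cam(model, spec, img, "conv3_relu", target_class=1)
        act = model.forward(np.asarray(img, np.float32)[None] / 255.0,
                            capture={"conv3_relu"})["conv3_relu"][0, :, :, 7]
        assert act.max() > 0
        assert np.allclose(cam.heatmap, act / act.max(), atol=1e-5)

    def test_non_spatial_layer_rejected(self, tiny):
        model, spec = tiny
        with pytest.raises(ConfigError):
            grad_cam(model, spec, np.zeros((64, 64, 3), np.uint8), "pool")

    def test_heat_concentrates_on_the_organ(self, object_bank):
        """A trained network's activation should track the organ, not the
        background: >=60% of Grad-CAM energy within the object's
        receptive-field support, averaged over 20 held-out images."""
        images, labels = object_bank["seed"]
        model, spec = build_backbone("tiny", 5, rng_seed=0)
        tr = np.arange(len(images)) % 5 != 0
        cfg = TrainConfig(batch_size=16, learning_rate=0.02, validation_frequency=20,
                          max_epochs=25, freeze_policy="none", rng_seed=0)
        finetune(model, spec, ([images[i] for i in np.where(tr)[0]], labels[tr]),
                 ([images[i] for i in np.where(~tr)[0]], labels[~tr]), cfg)
        from phenofuse.synthetic import generate_phenotypes
        phenos = generate_phenotypes(5, rng_seed=2)[0]
        fracs = []
        for s in range(20):
            k = s % 5
            scan, _ = render_scan(phenos[k], "seed", 3, rng_seed=4000 + s)
            obj = segment_scan(scan)[0]
            cam = grad_cam(model, spec, obj.pixels, "conv3_relu", target_class=k)
            # conv3_relu receptive field is ~18 px at the 64-px input
            fracs.append(heat_inside_fraction(cam, obj.mask, rf_halo_px=9))
        assert np.mean(fracs) >= 0.6


class TestTsne:
    def _two_clusters(self, n=40, d=10):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(n, d))
        b = rng.normal(12, 1, size=(n, d))
        return np.vstack([a, b]).astype(np.float32), np.array([0] * n + [1] * n)

    def test_separated_clusters_stay_separated(self):
        x, labels = self._two_clusters()
        emb = tsne_embed(x, dims=2, perplexity=10, rng_seed=0)
        from sklearn.metrics import silhouette_score
        assert emb.coords.shape == (80, 2)
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_deterministic_given_seed(self):
        x, _ = self._two_clusters(n=20)
        a = tsne_embed(x, dims=3, perplexity=5, rng_seed=7)
        b = tsne_embed(x, dims=3, perplexity=5, rng_seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            tsne_embed(np.zeros((10, 4), np.float32), perplexity=30)

    def test_feature_matrix_input(self):
        x, _ = self._two_clusters(n=20)
        fm = FeatureMatrix(x, [str(i) for i in range(40)], "pool", "tiny")
        emb = tsne_embed(fm, dims=2, perplexity=5, rng_seed=1)
        assert emb.source == "pool"


class TestClusterTree:
    def test_identical_centroids_merge_first_at_zero_height(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        tree = build_cluster_tree(x, ["a", "b", "c"])
        assert tree.first_merge() == ("a", "b")
        assert tree.merges[0, 2] == 0.0

    def test_collinear_points_merge_nearest_pair_first(self):
        x = np.array([[0.0], [1.0], [10.0]])
        tree = build_cluster_tree(x, ["p", "q", "r"])
        assert tree.first_merge() == ("p", "q")

    def test_merge_count_and_monotone_heights(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 5))
        tree = build_cluster_tree(x, [f"c{i}" for i in range(8)])
        assert tree.merges.shape[0] == 7
        assert (np.diff(tree.merges[:, 2]) >= -1e-9).all()

    def test_via_3d_reduction_runs_and_is_seeded(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(k * 8, 0.5, size=(1, 6)) for k in range(10)])
        labels = [f"c{i}" for i in range(10)]
        a = build_cluster_tree(x, labels, via_3d=True, rng_seed=0)
        b = build_cluster_tree(x, labels, via_3d=True, rng_seed=0)
        assert np.allclose(a.merges, b.merges)

    def test_newick_roundtrips_through_scikit_bio(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 4))
        labels = [f"L{i}" for i in range(6)]
        tree = build_cluster_tree(x, labels)
        from skbio import TreeNode
        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(labels)

    def test_bisecting_kmeans_mode(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 0.3, (3, 4)), rng.normal(9, 0.3, (3, 4))])
        labels = [f"c{i}" for i in range(6)]
        tree = build_cluster_tree(x, labels, method="bisecting_kmeans", rng_seed=0)
        assert tree.merges.shape[0] == 5
        assert (np.diff(tree.merges[:, 2]) >= -1e-9).all()
        # the two tight triplets should each share a low subtree
        h_within = tree.cophenetic_height("c0", "c1")
        h_across = tree.cophenetic_height("c0", "c4")
        assert h_within < h_across

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            build_cluster_tree(np.zeros((1, 3)), ["only"])

    def test_class_mean_features_sorted(self):
        fm = FeatureMatrix(np.array([[1.0], [3.0], [2.0]], np.float32),
                           ["r0", "r1", "r2"], "pool", "tiny")
        means, classes = class_mean_features(fm, ["b", "a", "b"])
        assert classes == ["a", "b"]
        assert np.allclose(means, [[3.0], [1.5]])
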