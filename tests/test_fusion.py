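import numpy as np
import pytest

from phenofuse.backbones import FeatureMatrix
from phenofuse.errors import ConfigError, DataError, ShapeError
from phenofuse.fusion import (
    FusedPairSet, PairingMap, fuse, make_pairs, predict, train_classifier,
)
from phenofuse.manifest import new_manifest


def _organ_manifest(counts: dict[str, int], organ: str, split="test"):
    rows = []
    for cls, n in counts.items():
        for i in range(n):
            rows.append({"path": f"{cls}_{organ}_{i:04d}.png", "class": cls,
                         "organ": organ, "scan_id": "s", "object_index": i,
                         "area_px": 1, "split": split, "is_augmented": False,
                         "source_path": ""})
    return new_manifest(rows)


class TestMakePairs:
    def test_equal_lengths_pair_identity(self):
        pods = _organ_manifest({"a": 10, "b": 10}, "pod")
        seeds = _organ_manifest({"a": 10, "b": 10}, "seed")
        pm = make_pairs(pods, seeds, "test", pairs_per_class=10)
        for cls in ("a", "b"):
            cls_pairs = [(p, s) for p, s, c in pm.pairs if c == cls]
            for i, (p, s) in enumerate(cls_pairs):
                assert p == f"{cls}_pod_{i:04d}.png" and s == f"{cls}_seed_{i:04d}.png"

    def test_shorter_list_cycles(self):
        pods = _organ_manifest({"a": 80}, "pod")
        seeds = _organ_manifest({"a": 100}, "seed")
        pm = make_pairs(pods, seeds, "test", pairs_per_class=100)
        assert len(pm.pairs) == 100
        for i, (p, s, _) in enumerate(pm.pairs):
            assert p == f"a_pod_{i % 80:04d}.png" and s == f"a_seed_{i:04d}.png"

    def test_random_strategy_deterministic_and_unique(self):
        pods = _organ_manifest({"a": 6}, "pod")
        seeds = _organ_manifest({"a": 7}, "seed")
        a = make_pairs(pods, seeds, "test", strategy="random", pairs_per_class=20,
                       rng_seed=3)
        b = make_pairs(pods, seeds, "test", strategy="random", pairs_per_class=20,
                       rng_seed=3)
        assert a.pairs == b.pairs
        assert len(set(a.pairs)) == 20

    def test_class_missing_in_one_organ(self):
        pods = _organ_manifest({"a": 5}, "pod")
        seeds = _organ_manifest({"a": 5, "b": 5}, "seed")
        with pytest.raises(DataError):
            make_pairs(pods, seeds, "test")

    def test_default_pairs_per_class_is_smaller_count(self):
        pods = _organ_manifest({"a": 4}, "pod")
        seeds = _organ_manifest({"a": 9}, "seed")
        assert len(make_pairs(pods, seeds, "test").pairs) == 4


def _features(prefix, n, d, offset=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureMatrix(rng.normal(offset, 1, size=(n, d)).astype(np.float32),
                         [f"{prefix}_{i:04d}.png" for i in range(n)], "pool", "tiny")


class TestFuse:
    def _pairing(self, n, cls="a"):
        return PairingMap([(f"p_{i:04d}.png", f"s_{i:04d}.png", cls) for i in range(n)],
                          "round_robin", 0)

    def test_width_is_sum_of_branches(self):
        fused = fuse(_features("p", 5, 2048), _features("s", 5, 2048), self._pairing(5))
        assert fused.values.shape == (5, 4096)
        assert fused.d_pod == fused.d_seed == 2048

    def test_block_structure(self):
        pod = FeatureMatrix(np.zeros((1, 3), np.float32), ["p_0000.png"], "pool", "tiny")
        v = np.array([[1.0, 2.0, 3.0, 4.0]], np.float32)
        seed = FeatureMatrix(v, ["s_0000.png"], "pool", "tiny")
        fused = fuse(pod, seed, self._pairing(1))
        assert np.array_equal(fused.values, [[0, 0, 0, 1, 2, 3, 4]])

    def test_column_means_concatenate_under_identity_pairing(self):
        pod, seed = _features("p", 20, 4, seed=1), _features("s", 20, 6, seed=2)
        fused = fuse(pod, seed, self._pairing(20))
        assert np.allclose(fused.values.mean(0),
                           np.concatenate([pod.values.mean(0), seed.values.mean(0)]),
                           atol=1e-6)

    def test_missing_row_id(self):
        with pytest.raises(DataError):
            fuse(_features("p", 3, 4), _features("s", 3, 4), self._pairing(5))


def _gaussian_fused(n_per_class=25, d=16, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    values, labels = [], []
    for k, cls in enumerate(("a", "b", "c")):
        mu = np.zeros(d)
        mu[k] = sep
        values.append(rng.normal(mu, 1, size=(n_per_class, d)))
        labels += [cls] * n_per_class
    pairing = PairingMap([(f"p{i}", f"s{i}", c) for i, c in enumerate(labels)],
                         "round_robin", 0)
    return FusedPairSet(np.vstack(values).astype(np.float32), np.array(labels),
                        pairing, d_pod=d // 2, d_seed=d - d // 2)


class TestClassifier:
    def test_separable_classes_fit_perfectly(self):
        train = _gaussian_fused()
        model = train_classifier(train)
        assert (predict(model, train) == train.labels).all()

    def test_duplicated_training_set_same_decisions(self):
        train = _gaussian_fused()
        dup = FusedPairSet(np.vstack([train.values, train.values]),
                           np.concatenate([train.labels, train.labels]),
                           train.pairing, train.d_pod, train.d_seed)
        probe = _gaussian_fused(seed=9).values
        assert (predict(train_classifier(train), probe)
                == predict(train_classifier(dup), probe)).all()

    def test_deterministic_refit(self):
        train = _gaussian_fused()
        a, b = train_classifier(train), train_classifier(train)
        assert a.n_support == b.n_support
        probe = _gaussian_fused(seed=5).values
        assert (predict(a, probe) == predict(b, probe)).all()

    def test_single_class_rejected(self):
        train = _gaussian_fused()
        one = FusedPairSet(train.values[:10], np.array(["a"] * 10), train.pairing,
                           train.d_pod, train.d_seed)
        with pytest.raises(DataError):
            train_classifier(one)

    def test_rbf_kernel_supported_and_unknown_rejected(self):
        train = _gaussian_fused()
        assert train_classifier(train, kernel="rbf").kernel == "rbf"
        with pytest.raises(ConfigError):
            train_classifier(train, kernel="poly")


class TestPredict:
    def test_width_mismatch(self):
        model = train_classifier(_gaussian_fused())
        with pytest.raises(ShapeError):
            predict(model, np.zeros((2, 5), np.float32))

    def test_row_independence_under_permutation(self):
        model = train_classifier(_gaussian_fused())
        probe = _gaussian_fused(seed=4).values
        perm = np.random.default_rng(0).permutation(len(probe))
        assert (predict(model, probe)[perm] == predict(model, probe[perm])).all()

    def test_single_row(self):
        model = train_classifier(_gaussian_fused())
        out = predict(model, _gaussian_fused().values[0])
        assert out.shape == (1,)

    def test_prediction_does_not_refit_standardizer(self):
        train = _gaussian_fused()
        model = train_classifier(train)
        mean_before = model._scaler.mean_.copy()
        predict(model, _gaussian_fused(seed=8))
        assert np.array_equal(model._scaler.mean_, mean_before)

    def test_zeroing_seed_block_tracks_pod_only_classifier(self):
        train = _gaussian_fused(n_per_class=60, sep=8.0)
        test = _gaussian_fused(n_per_class=60, sep=8.0, seed=3)
        fused_model = train_classifier(train)
        ablated = test.values.copy()
        ablated[:, train.d_pod:] = 0.0
        acc_ablated = (predict(fused_model, ablated) == test.labels).mean()
        pod_train = FusedPairSet(train.values[:, :train.d_pod], train.labels,
                                 train.pairing, train.d_pod, 0)
        pod_model = train_classifier(pod_train)
        acc_pod = (predict(pod_model, test.values[:, :train.d_pod])
                   == test.labels).mean()
        assert abs(acc_ablated - acc_pod) <= 0.03
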