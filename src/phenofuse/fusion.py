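"""Pod-seed pairing, feature concatenation, and SVM classification.

The dual-branch design extracts one feature vector per organ image and
concatenates a pod vector with a seed vector of the same class into one
fused sample (pod block first). How individual pod images are matched to
seed images is not biologically meaningful — objects are scanned loose —
so pairing is explicit and deterministic: ``round_robin`` cycles the
shorter organ list, ``random`` samples unique pairs with a seeded RNG,
``exhaustive_capped`` enumerates the cross product up to a cap.

Classification follows the classic deep-features recipe: per-dimension
z-scoring fitted on the training pairs only, then a one-vs-one SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .backbones import FeatureMatrix
from .errors import ConfigError, DataError, ShapeError

PAIR_STRATEGIES = ("round_robin", "random", "exhaustive_capped")


@dataclass
class PairingMap:
    pairs: list[tuple[str, str, str]]   # (pod_row_id, seed_row_id, class_label)
    strategy: str
    rng_seed: int

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise DataError("duplicate pairs in pairing map")

    @property
    def labels(self) -> list[str]:
        return [c for _, _, c in self.pairs]


@dataclass
class FusedPairSet:
    values: np.ndarray                  # m x (d_pod + d_seed)
    labels: np.ndarray                  # m class labels
    pairing: PairingMap
    d_pod: int = 0
    d_seed: int = 0


def _split_ids(manifest: pd.DataFrame, split: str) -> dict[str, list[str]]:
    sub = manifest[manifest["split"] == split]
    return {cls: sorted(g["path"].tolist()) for cls, g in sub.groupby("class")}


def make_pairs(pod_manifest: pd.DataFrame, seed_manifest: pd.DataFrame, split: str,
               strategy: str = "round_robin", pairs_per_class: int | None = None,
               rng_seed: int = 0) -> PairingMap:
    """Build a per-class pod-seed pairing for one split.

    ``pairs_per_class=None`` defaults to the smaller organ count per class.
    Round-robin pairs sorted lists index-by-index, cycling the shorter one,
    so equal-length classes pair (i, i).
    """
    if strategy not in PAIR_STRATEGIES:
        raise ConfigError(f"unknown pairing strategy {strategy!r}")
    pods = _split_ids(pod_manifest, split)
    seeds = _split_ids(seed_manifest, split)
    classes = sorted(set(pods) | set(seeds))
    missing = [c for c in classes if c not in pods or c not in seeds]
    if missing:
        raise DataError(f"classes present in only one organ for split {split!r}: {missing}")
    rng = np.random.default_rng(rng_seed)
    pairs: list[tuple[str, str, str]] = []
    for cls in classes:
        p, s = pods[cls], seeds[cls]
        n = pairs_per_class if pairs_per_class is not None else min(len(p), len(s))
        if strategy == "round_robin":
            pairs += [(p[i % len(p)], s[i % len(s)], cls) for i in range(n)]
        elif strategy == "exhaustive_capped":
            all_pairs = [(pi, si, cls) for pi in p for si in s]
            pairs += all_pairs[:n]
        else:  # random, unique pairs until exhausted
            total = len(p) * len(s)
            if n > total:
                raise DataError(f"class {cls}: {n} unique pairs requested, only {total} exist")
            flat = rng.choice(total, size=n, replace=False)
            pairs += [(p[k // len(s)], s[k % len(s)], cls) for k in sorted(flat)]
    return PairingMap(pairs=pairs, strategy=strategy, rng_seed=rng_seed)


def fuse(pod_features: FeatureMatrix, seed_features: FeatureMatrix,
         pairing: PairingMap) -> FusedPairSet:
    """Concatenate paired branch vectors: row k = [pod_k | seed_k]."""
    pod_idx = {rid: i for i, rid in enumerate(pod_features.row_ids)}
    seed_idx = {rid: i for i, rid in enumerate(seed_features.row_ids)}
    for pid, sid, _ in pairing.pairs:
        if pid not in pod_idx:
            raise DataError(f"pod row id {pid!r} missing from pod feature matrix")
        if sid not in seed_idx:
            raise DataError(f"seed row id {sid!r} missing from seed feature matrix")
    pod_rows = pod_features.values[[pod_idx[p] for p, _, _ in pairing.pairs]]
    seed_rows = seed_features.values[[seed_idx[s] for _, s, _ in pairing.pairs]]
    values = np.hstack([pod_rows, seed_rows])
    return FusedPairSet(values=values, labels=np.array(pairing.labels), pairing=pairing,
                        d_pod=pod_features.values.shape[1],
                        d_seed=seed_features.values.shape[1])


@dataclass
class ClassifierModel:
    """Standardizer + one-vs-one SVM, fitted only through :func:`train_classifier`."""

    kernel: str
    C: float
    _scaler: StandardScaler = field(repr=False)
    _svm: SVC = field(repr=False)
    label_map: list[str] = field(default_factory=list)
    n_features: int = 0

    @property
    def n_support(self) -> int:
        return int(self._svm.n_support_.sum())


def train_classifier(train: FusedPairSet, kernel: str = "linear", C: float = 1.0,
                     ) -> ClassifierModel:
    """Fit z-scoring on the training pairs, then a one-vs-one SVM."""
    if kernel not in ("linear", "rbf"):
        raise ConfigError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) < 2:
        raise DataError("training set must contain at least 2 classes")
    if counts.min() < 2:
        raise DataError("every class needs at least 2 training samples")
    scaler = StandardScaler().fit(train.values)
    svm = SVC(kernel=kernel, C=C, decision_function_shape="ovo", random_state=0)
    svm.fit(scaler.transform(train.values), train.labels)
    return ClassifierModel(kernel=kernel, C=C, _scaler=scaler, _svm=svm,
                           label_map=[str(c) for c in svm.classes_],
                           n_features=train.values.shape[1])


def predict(model: ClassifierModel, data: FusedPairSet | np.ndarray) -> np.ndarray:
    """Predict one class label per fused row."""
    values = data.values if isinstance(data, FusedPairSet) else np.asarray(data)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.n_features:
        raise ShapeError(
            f"fused width {values.shape[1]} does not match training width {model.n_features}")
    return model._svm.predict(model._scaler.transform(values))
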