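"""Model interpretation: Grad-CAM, t-SNE embedding, class clustering tree.

Grad-CAM locates the image regions driving a class score: channel
activations at a spatial layer are weighted by the spatially averaged
gradient of the class logit, summed, rectified and min-max normalized.
t-SNE projects branch or fused features to 2-D/3-D for visual inspection
of line similarity. The clustering tree summarizes class-level relatedness
by hierarchical agglomeration over per-class mean feature vectors
(optionally after a 3-D t-SNE reduction, mirroring how such dendrograms
are usually drawn from low-dimensional embeddings); a recursive bisecting
k-means tree is available as an alternative construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .backbones import BackboneSpec, FeatureMatrix, preprocess
from .errors import ConfigError, DataError
from .nn import Network


# --------------------------------------------------------------------------
# Grad-CAM

@dataclass
class GradCamMap:
    heatmap: np.ndarray      # layer-resolution map, values in [0, 1]
    overlay: np.ndarray      # bilinearly upsampled to input resolution
    target_class: int
    layer_name: str


def grad_cam(model: Network, spec: BackboneSpec, image, layer_name: str,
             target_class: int | None = None) -> GradCamMap:
    """Class activation map at a spatial layer for one image.

    ``target_class=None`` uses the predicted class. The map is the ReLU of
    the gradient-weighted channel sum, normalized to [0, 1] (all-zero maps
    stay zero).
    """
    if layer_name not in model:
        raise ConfigError(f"unknown layer {layer_name!r}")
    x = preprocess([np.asarray(image)], spec)
    acts = model.forward(x, capture={layer_name, spec.logits_node}, retain=True)
    layer_act = acts[layer_name]
    if layer_act.ndim != 4:
        raise ConfigError(f"layer {layer_name!r} has no spatial activations "
                          f"(shape {layer_act.shape})")
    logits = acts[spec.logits_node]
    if target_class is None:
        target_class = int(logits.argmax())
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    grads = model.backward({spec.logits_node: seed}, until=layer_name)
    g = grads[layer_name]                     # (1, h, w, c)
    weights = g.mean(axis=(1, 2))             # (1, c)
    cam = np.maximum((layer_act * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    h, w, _ = spec.input_size
    overlay = resize(cam, (h, w), order=1, preserve_range=True)
    return GradCamMap(heatmap=cam, overlay=overlay,
                      target_class=target_class, layer_name=layer_name)


def heat_inside_fraction(cam: GradCamMap, object_mask: np.ndarray,
                         rf_halo_px: int = 0) -> float:
    """Fraction of Grad-CAM energy attributable to the object.

    The overlay (input resolution) is compared against the object support:
    pixels with any object coverage after downsampling the mask to the
    overlay size, dilated by ``rf_halo_px``. A conv activation is driven by
    its entire receptive field, so when judging whether a *coarse* CAM
    tracks the organ rather than the background, the support is widened by
    the feature layer's receptive-field radius at input resolution.
    """
    from scipy.ndimage import binary_dilation

    h, w = cam.overlay.shape
    support = resize(np.asarray(object_mask, dtype=float), (h, w), order=1) > 0.02
    if rf_halo_px > 0:
        support = binary_dilation(support, iterations=int(rf_halo_px))
    total = cam.overlay.sum()
    if total <= 0:
        return 0.0
    return float(cam.overlay[support].sum() / total)


# --------------------------------------------------------------------------
# t-SNE

@dataclass
class EmbeddingResult:
    coords: np.ndarray
    perplexity: float
    rng_seed: int
    source: str


def tsne_embed(features: FeatureMatrix | np.ndarray, dims: int = 2,
               perplexity: float = 30.0, rng_seed: int = 0,
               source: str = "") -> EmbeddingResult:
    """Seeded t-SNE projection to 2-D or 3-D."""
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if dims not in (2, 3):
        raise ConfigError("dims must be 2 or 3")
    n = values.shape[0]
    if n <= 3 * perplexity:
        raise DataError(f"t-SNE needs n > 3*perplexity; got n={n}, perplexity={perplexity}")
    ts = TSNE(n_components=dims, perplexity=perplexity, random_state=rng_seed,
              init="pca", max_iter=500)
    coords = ts.fit_transform(values.astype(np.float64))
    if not np.isfinite(coords).all():
        raise DataError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(coords=coords, perplexity=perplexity, rng_seed=rng_seed,
                           source=source or (features.layer_name
                                             if isinstance(features, FeatureMatrix) else ""))


# --------------------------------------------------------------------------
# clustering tree

@dataclass
class ClusterTree:
    """Dendrogram over class labels as a scipy-style merge list.

    ``merges[i] = (a, b, height, size)`` merges nodes a and b (leaves are
    0..K-1 in ``leaf_labels`` order; internal node i is K+i).
    """

    merges: np.ndarray
    leaf_labels: list[str]
    method: str

    def first_merge(self) -> tuple[str, str]:
        """The pair of leaf-descendant sets merged at the lowest height."""
        a, b = int(self.merges[0, 0]), int(self.merges[0, 1])
        return tuple(sorted((self.leaf_labels[a], self.leaf_labels[b])))

    def cophenetic_height(self, label_a: str, label_b: str) -> float:
        """Height at which two leaves first share a cluster."""
        k = len(self.leaf_labels)
        members = {i: {i} for i in range(k)}
        ia, ib = self.leaf_labels.index(label_a), self.leaf_labels.index(label_b)
        for i, (a, b, h, _) in enumerate(self.merges):
            merged = members[int(a)] | members[int(b)]
            members[k + i] = merged
            if ia in merged and ib in merged:
                return float(h)
        raise DataError("labels never merge (malformed tree)")

    def to_newick(self) -> str:
        k = len(self.leaf_labels)
        heights = {i: 0.0 for i in range(k)}
        reps: dict[int, str] = {i: self.leaf_labels[i] for i in range(k)}
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            reps[k + i] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
            heights[k + i] = float(h)
        return reps[k + len(self.merges) - 1] + ";"


def class_mean_features(features: FeatureMatrix, labels) -> tuple[np.ndarray, list[str]]:
    """Per-class mean feature vectors, classes sorted."""
    labels = np.asarray([str(x) for x in labels])
    classes = sorted(set(labels))
    means = np.vstack([features.values[labels == c].mean(axis=0) for c in classes])
    return means, classes


def build_cluster_tree(class_features: np.ndarray, leaf_labels: list[str],
                       via_3d: bool = False, linkage: str = "ward",
                       rng_seed: int = 0, method: str = "agglomerative",
                       perplexity: float | None = None) -> ClusterTree:
    """Hierarchical tree over class centroids.

    ``via_3d`` first reduces the centroids to 3-D with t-SNE (perplexity
    clamped to (K-1)/3 so the embedding is defined for small K), then
    agglomerates with the chosen linkage (default Ward on Euclidean).
    ``method="bisecting_kmeans"`` instead builds the tree top-down by
    recursive 2-means splits, with heights given by within-cluster
    dispersion.
    """
    x = np.asarray(class_features, dtype=np.float64)
    k = x.shape[0]
    if k < 2:
        raise DataError("clustering tree needs at least 2 classes")
    if len(leaf_labels) != k:
        raise DataError("leaf_labels length must match the number of class rows")
    if via_3d:
        p = perplexity if perplexity is not None else max(2.0, (k - 1) / 3.0)
        p = min(p, (k - 1) / 3.0)
        if k <= 3 * p:
            p = (k - 1) / 3.0
        x = tsne_embed(x, dims=3, perplexity=max(1.0, p), rng_seed=rng_seed).coords
    if method == "agglomerative":
        merges = hierarchy.linkage(x, method=linkage)
        return ClusterTree(merges=merges, leaf_labels=list(leaf_labels),
                           method=f"agglomerative/{linkage}" + ("+tsne3d" if via_3d else ""))
    if method != "bisecting_kmeans":
        raise ConfigError(f"unknown tree method {method!r}")
    return _bisecting_tree(x, list(leaf_labels), rng_seed)


def _bisecting_tree(x: np.ndarray, leaf_labels: list[str], rng_seed: int) -> ClusterTree:
    """Top-down 2-means tree converted to a bottom-up merge list."""
    k = x.shape[0]

    def split(indices: np.ndarray):
        if len(indices) == 1:
            return int(indices[0]), 0.0, 1
        if len(indices) == 2:
            a, b = (int(indices[0]), 0.0, 1), (int(indices[1]), 0.0, 1)
            h = float(np.linalg.norm(x[indices[0]] - x[indices[1]]))
            return _emit(a, b, h)
        km = KMeans(n_clusters=2, random_state=rng_seed, n_init=10).fit(x[indices])
        lab = km.labels_
        if lab.min() == lab.max():        # degenerate: identical points
            left, right = indices[:1], indices[1:]
        else:
            left, right = indices[lab == 0], indices[lab == 1]
        h = float(np.sqrt(((x[indices] - x[indices].mean(0)) ** 2).sum(1).mean()))
        return _emit(split(left), split(right), h)

    merges: list[list[float]] = []

    def _emit(a, b, h):
        ida, ha, na = a
        idb, hb, nb = b
        h = max(h, ha, hb)               # keep heights monotone
        merges.append([ida, idb, h, na + nb])
        return k + len(merges) - 1, h, na + nb

    split(np.arange(k))
    z = np.array(merges, dtype=float)
    order = np.argsort(z[:, 2], kind="stable")
    # renumber internal nodes after sorting by height
    remap = {int(k + old): k + new for new, old in enumerate(order)}
    z = z[order]
    for row in z:
        for j in (0, 1):
            row[j] = remap.get(int(row[j]), int(row[j]))
    return ClusterTree(merges=z, leaf_labels=leaf_labels, method="bisecting_kmeans")
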