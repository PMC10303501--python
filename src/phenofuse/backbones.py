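"""CNN backbones, head fine-tuning, and named-layer feature extraction.

Five backbones are registered: the four classic transfer-learning
architectures (AlexNet, GoogLeNet, ResNet18, ResNet50) and a small
``tiny`` model for fast end-to-end runs. Each declares three feature
layers — an interior spatial layer, the global-pooling layer used for
fusion, and the class-probability layer — with their flattened output
widths, which the forward pass must realize exactly.

Weights are randomly initialized (He) from a seed; there is no bundled
pretrained-weight source, so ``weights="pretrained"`` raises. Random
backbones still honour every dimensional contract and, combined with a
trained head or a downstream SVM, act as fixed random feature extractors.

Notes on layer naming: the ResNet50 interior layer is exposed under its
conventional name ``activation_48_relu`` and is placed at the last
conv4-stage bottleneck's 3x3 ReLU, the layer whose flattened width is
14*14*256 = 50176; AlexNet's ``fc8`` is the retrained head, so its width
is ``num_classes`` (its ImageNet-shaped 4096 printing is not reproducible
with a replaced head — ``relu7`` is the 4096-wide AlexNet fusion layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigError, DataError, ShapeError
from .nn import (Add, Concat, Conv2d, Flatten, GlobalAvgPool, Linear, MaxPool2d,
                 Network, Node, ReLU, SGD, Softmax, cross_entropy_with_logits)
from .nn.graph import INPUT

BACKBONE_NAMES = ("alexnet", "googlenet", "resnet18", "resnet50", "tiny")


@dataclass
class BackboneSpec:
    name: str
    input_size: tuple[int, int, int]
    num_classes: int
    feature_layers: dict[str, int]      # layer name -> flattened feature width
    head_input: str                     # node feeding the classification head
    logits_node: str
    softmax_node: str
    notes: dict = field(default_factory=dict)


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.0003
    validation_frequency: int = 64
    max_epochs: int = 100
    freeze_policy: str = "freeze_all_conv"   # or "none"
    momentum: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.validation_frequency, self.max_epochs) <= 0 \
                or self.learning_rate <= 0:
            raise ConfigError("train config values must be positive")
        if self.freeze_policy not in ("freeze_all_conv", "none"):
            raise ConfigError(f"unknown freeze_policy {self.freeze_policy!r}")


@dataclass
class FeatureMatrix:
    """Row-aligned n x d feature array extracted at one named layer."""

    values: np.ndarray
    row_ids: list[str]
    layer_name: str
    backbone_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ShapeError("feature matrix rows must align with row_ids")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite values in feature matrix")

    def to_csv(self, path):
        import pandas as pd
        df = pd.DataFrame(self.values)
        df.insert(0, "row_id", self.row_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layer_name="", backbone_name=""):
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df.drop(columns=["row_id"]).to_numpy(np.float32),
                   df["row_id"].astype(str).tolist(), layer_name, backbone_name)


# --------------------------------------------------------------------------
# graph builders

class _Builder:
    def __init__(self, rng):
        self.nodes: list[Node] = []
        self.cur = INPUT
        self.rng = rng

    def add(self, name, layer, inputs=None):
        self.nodes.append(Node(name, layer, list(inputs) if inputs else [self.cur]))
        self.cur = name
        return name

    def conv(self, name, c_in, c_out, k, s=1, p=0, inputs=None):
        return self.add(name, Conv2d(c_in, c_out, k, s, p, rng=self.rng), inputs)

    def relu(self, name):
        return self.add(name, ReLU())

    def maxpool(self, name, k, s, p=0):
        return self.add(name, MaxPool2d(k, s, p))


def _build_tiny(K, rng):
    b = _Builder(rng)
    b.conv("conv1", 3, 16, 3, 1, 1); b.relu("relu1"); b.maxpool("pool1", 2, 2)
    b.conv("conv2", 16, 32, 3, 1, 1); b.relu("relu2"); b.maxpool("pool2", 2, 2)
    b.conv("conv3", 32, 32, 3, 1, 1); b.relu("conv3_relu")
    b.add("pool", GlobalAvgPool())
    b.add("fc", Linear(32, K, rng=rng))
    b.add("prob", Softmax())
    spec = BackboneSpec("tiny", (64, 64, 3), K,
                        {"conv3_relu": 16 * 16 * 32, "pool": 32, "prob": K},
                        head_input="pool", logits_node="fc", softmax_node="prob")
    return Network(b.nodes), spec


def _build_alexnet(K, rng):
    b = _Builder(rng)
    b.conv("conv1", 3, 96, 11, 4); b.relu("relu1"); b.maxpool("pool1", 3, 2)
    b.conv("conv2", 96, 256, 5, 1, 2); b.relu("relu2"); b.maxpool("pool2", 3, 2)
    b.conv("conv3", 256, 384, 3, 1, 1); b.relu("relu3")
    b.conv("conv4", 384, 384, 3, 1, 1); b.relu("relu4")
    b.conv("conv5", 384, 256, 3, 1, 1); b.relu("relu5"); b.maxpool("pool5", 3, 2)
    b.add("flatten", Flatten())
    b.add("fc6", Linear(6 * 6 * 256, 4096, rng=rng)); b.relu("relu6")
    b.add("fc7", Linear(4096, 4096, rng=rng)); b.relu("relu7")
    b.add("fc8", Linear(4096, K, rng=rng))
    b.add("prob", Softmax())
    spec = BackboneSpec("alexnet", (227, 227, 3), K,
                        {"fc8": K, "relu7": 4096, "prob": K},
                        head_input="relu7", logits_node="fc8", softmax_node="prob",
                        notes={"fc8_as_printed": 4096})
    return Network(b.nodes), spec


def _basic_block(b, blk, c_in, c_out, stride):
    entry = b.cur
    b.conv(f"{blk}_branch2a", c_in, c_out, 3, stride, 1)
    b.relu(f"{blk}_branch2a_relu")
    b.conv(f"{blk}_branch2b", c_out, c_out, 3, 1, 1)
    if stride != 1 or c_in != c_out:
        b.conv(f"{blk}_branch1", c_in, c_out, 1, stride, 0, inputs=[entry])
        shortcut = b.cur
    else:
        shortcut = entry
    b.add(f"{blk}_add", Add(), inputs=[f"{blk}_branch2b", shortcut])
    b.relu(f"{blk}_relu")


def _build_resnet18(K, rng):
    b = _Builder(rng)
    b.conv("conv1", 3, 64, 7, 2, 3); b.relu("conv1_relu"); b.maxpool("pool1", 3, 2, 1)
    c_in = 64
    for stage, c_out in zip(range(2, 6), (64, 128, 256, 512)):
        for i, blk in enumerate("ab"):
            stride = 2 if (i == 0 and stage > 2) else 1
            _basic_block(b, f"res{stage}{blk}", c_in, c_out, stride)
            c_in = c_out
    b.add("pool5", GlobalAvgPool())
    b.add("fc", Linear(512, K, rng=rng))
    b.add("prob", Softmax())
    spec = BackboneSpec("resnet18", (224, 224, 3), K,
                        {"res5b_relu": 7 * 7 * 512, "pool5": 512, "prob": K},
                        head_input="pool5", logits_node="fc", softmax_node="prob")
    return Network(b.nodes), spec


def _bottleneck(b, blk, c_in, mid, stride, relu_2b_name=None):
    entry = b.cur
    b.conv(f"{blk}_branch2a", c_in, mid, 1)
    b.relu(f"{blk}_branch2a_relu")
    b.conv(f"{blk}_branch2b", mid, mid, 3, stride, 1)
    b.relu(relu_2b_name or f"{blk}_branch2b_relu")
    b.conv(f"{blk}_branch2c", mid, 4 * mid, 1)
    if stride != 1 or c_in != 4 * mid:
        b.conv(f"{blk}_branch1", c_in, 4 * mid, 1, stride, 0, inputs=[entry])
        shortcut = b.cur
    else:
        shortcut = entry
    b.add(f"{blk}_add", Add(), inputs=[f"{blk}_branch2c", shortcut])
    b.relu(f"{blk}_relu")


def _build_resnet50(K, rng):
    b = _Builder(rng)
    b.conv("conv1", 3, 64, 7, 2, 3); b.relu("conv1_relu"); b.maxpool("pool1", 3, 2, 1)
    c_in = 64
    stage_cfg = ((2, 64, 3), (3, 128, 4), (4, 256, 6), (5, 512, 3))
    for stage, mid, n_blocks in stage_cfg:
        for i in range(n_blocks):
            blk = f"res{stage}{'abcdef'[i]}"
            stride = 2 if (i == 0 and stage > 2) else 1
            # the last conv4 3x3 ReLU is the published interior feature layer
            relu_2b = "activation_48_relu" if (stage == 4 and i == n_blocks - 1) else None
            _bottleneck(b, blk, c_in, mid, stride, relu_2b_name=relu_2b)
            c_in = 4 * mid
    b.add("avg_pool", GlobalAvgPool())
    b.add("fc1000", Linear(2048, K, rng=rng))
    b.add("fc1000_softmax", Softmax())
    spec = BackboneSpec("resnet50", (224, 224, 3), K,
                        {"activation_48_relu": 14 * 14 * 256, "avg_pool": 2048,
                         "fc1000_softmax": K},
                        head_input="avg_pool", logits_node="fc1000",
                        softmax_node="fc1000_softmax")
    return Network(b.nodes), spec


_INCEPTION_CFG = {
    "3a": (64, (96, 128), (16, 32), 32), "3b": (128, (128, 192), (32, 96), 64),
    "4a": (192, (96, 208), (16, 48), 64), "4b": (160, (112, 224), (24, 64), 64),
    "4c": (128, (128, 256), (24, 64), 64), "4d": (112, (144, 288), (32, 64), 64),
    "4e": (256, (160, 320), (32, 128), 128), "5a": (256, (160, 320), (32, 128), 128),
    "5b": (384, (192, 384), (48, 128), 128),
}


def _inception(b, tag, c_in):
    c1, (c3r, c3), (c5r, c5), pp = _INCEPTION_CFG[tag]
    entry = b.cur
    pre = f"inception_{tag}"
    b.conv(f"{pre}-1x1", c_in, c1, 1, inputs=[entry]); b.relu(f"{pre}-relu_1x1")
    br1 = b.cur
    b.conv(f"{pre}-3x3_reduce", c_in, c3r, 1, inputs=[entry]); b.relu(f"{pre}-relu_3x3r")
    b.conv(f"{pre}-3x3", c3r, c3, 3, 1, 1); b.relu(f"{pre}-relu_3x3")
    br2 = b.cur
    b.conv(f"{pre}-5x5_reduce", c_in, c5r, 1, inputs=[entry]); b.relu(f"{pre}-relu_5x5r")
    b.conv(f"{pre}-5x5", c5r, c5, 5, 1, 2); b.relu(f"{pre}-relu_5x5")
    br3 = b.cur
    b.add(f"{pre}-pool", MaxPool2d(3, 1, 1), inputs=[entry])
    b.conv(f"{pre}-pool_proj", c_in, pp, 1); b.relu(f"{pre}-relu_pool_proj")
    br4 = b.cur
    b.add(f"{pre}-output", Concat(), inputs=[br1, br2, br3, br4])
    return c1 + c3 + c5 + pp


def _build_googlenet(K, rng):
    b = _Builder(rng)
    b.conv("conv1-7x7_s2", 3, 64, 7, 2, 3); b.relu("conv1-relu_7x7")
    b.maxpool("pool1-3x3_s2", 3, 2, 1)
    b.conv("conv2-3x3_reduce", 64, 64, 1); b.relu("conv2-relu_3x3_reduce")
    b.conv("conv2-3x3", 64, 192, 3, 1, 1); b.relu("conv2-relu_3x3")
    b.maxpool("pool2-3x3_s2", 3, 2, 1)
    c = 192
    for tag in ("3a", "3b"):
        c = _inception(b, tag, c)
    b.maxpool("pool3-3x3_s2", 3, 2, 1)
    for tag in ("4a", "4b", "4c", "4d", "4e"):
        c = _inception(b, tag, c)
    b.maxpool("pool4-3x3_s2", 3, 2, 1)
    for tag in ("5a", "5b"):
        c = _inception(b, tag, c)
    b.add("pool5-7x7_s1", GlobalAvgPool())
    b.add("loss3-classifier", Linear(1024, K, rng=rng))
    b.add("prob", Softmax())
    spec = BackboneSpec("googlenet", (224, 224, 3), K,
                        {"inception_5b-output": 7 * 7 * 1024, "pool5-7x7_s1": 1024,
                         "prob": K},
                        head_input="pool5-7x7_s1", logits_node="loss3-classifier",
                        softmax_node="prob")
    return Network(b.nodes), spec


_BUILDERS = {
    "tiny": _build_tiny, "alexnet": _build_alexnet, "googlenet": _build_googlenet,
    "resnet18": _build_resnet18, "resnet50": _build_resnet50,
}


def build_backbone(name: str, num_classes: int, weights: str = "random",
                   rng_seed: int = 0) -> tuple[Network, BackboneSpec]:
    """Construct a registered backbone with a ``num_classes`` head."""
    if name not in _BUILDERS:
        raise ConfigError(f"unknown backbone {name!r}; choose from {BACKBONE_NAMES}")
    if weights == "pretrained":
        raise ConfigError(
            "no pretrained weight source is bundled; build with weights='random' "
            "(random backbones act as fixed feature extractors)")
    if weights != "random":
        raise ConfigError(f"unknown weights mode {weights!r}")
    if num_classes < 2:
        raise ConfigError("num_classes must be >= 2")
    return _BUILDERS[name](num_classes, np.random.default_rng(rng_seed))


# --------------------------------------------------------------------------
# preprocessing and feature extraction

def preprocess(images, spec: BackboneSpec, mean: float = 0.0, std: float = 1.0,
               ) -> np.ndarray:
    """Resize uint8 RGB images to the backbone input and scale to [0, 1].

    The default normalization (mean 0, std 1 on the [0, 1] scale) keeps the
    black canvas background at exactly zero, so zero-bias convolutions stay
    silent off-object; other per-channel constants can be passed when
    matching an external training recipe.
    """
    h, w, _ = spec.input_size
    out = np.empty((len(images), h, w, 3), dtype=np.float32)
    for i, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ShapeError(f"image {i}: expected HxWx3, got {img.shape}")
        if img.shape[:2] != (h, w):
            img = resize(img, (h, w), order=1, preserve_range=True, anti_aliasing=True)
        out[i] = img
    return (out / 255.0 - mean) / std


def extract_features(model: Network, spec: BackboneSpec, layer_name: str, images,
                     row_ids: list[str] | None = None, batch_size: int = 16,
                     ) -> FeatureMatrix:
    """Forward a set of images and collect one named layer's activations.

    Rows follow input order; spatial activations are flattened row-major
    (H, W, C). Output width always equals the BackboneSpec declared width.
    """
    if layer_name not in spec.feature_layers:
        raise ConfigError(
            f"layer {layer_name!r} not a declared feature layer of {spec.name}: "
            f"{list(spec.feature_layers)}")
    n = len(images)
    d = spec.feature_layers[layer_name]
    values = np.empty((n, d), dtype=np.float32)
    for start in range(0, n, batch_size):
        batch = preprocess(images[start:start + batch_size], spec)
        acts = model.forward(batch, capture={layer_name})
        values[start:start + len(batch)] = acts[layer_name].reshape(len(batch), -1)
    if row_ids is None:
        row_ids = [str(i) for i in range(n)]
    return FeatureMatrix(values, list(row_ids), layer_name, spec.name)


def predict_proba(model: Network, spec: BackboneSpec, images, batch_size: int = 16):
    return extract_features(model, spec,
                            layer_name=list(spec.feature_layers)[-1],
                            images=images, batch_size=batch_size).values


# --------------------------------------------------------------------------
# fine-tuning

def _head_layer(model: Network, spec: BackboneSpec) -> Linear:
    return next(n.layer for n in model.nodes if n.name == spec.logits_node)


def finetune(model: Network, spec: BackboneSpec, train_data, val_data,
             config: TrainConfig | None = None):
    """Train the classification head (and optionally the whole model).

    ``train_data`` / ``val_data`` are ``(images, labels)`` with uint8 RGB
    images and integer labels. Under the default ``freeze_all_conv``
    policy only the head's weights change: features at the head-input
    layer are computed once and the head is trained on them with
    momentum-SGD. ``freeze_policy="none"`` backpropagates through the
    whole graph (practical for the tiny backbone).

    Returns ``(model, history)`` where history records train loss and
    validation accuracy every ``validation_frequency`` steps and at the
    end of training.
    """
    config = config or TrainConfig()
    (x_tr, y_tr), (x_va, y_va) = train_data, val_data
    if len(x_tr) == 0 or len(x_va) == 0:
        raise DataError("empty train or validation split")
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)
    rng = np.random.default_rng(config.rng_seed)
    history: list[dict] = []

    if config.freeze_policy == "freeze_all_conv":
        head = _head_layer(model, spec)
        for node in model.nodes:
            if node.layer is not head:
                node.layer.frozen = True
        f_tr = extract_features(model, spec, spec.head_input, x_tr).values
        f_va = extract_features(model, spec, spec.head_input, x_va).values
        # standardize head inputs for conditioning; folded back below so the
        # trained head keeps consuming raw backbone features
        mu = f_tr.mean(axis=0)
        sd = f_tr.std(axis=0) + 1e-6
        f_tr = (f_tr - mu) / sd
        f_va = (f_va - mu) / sd
        opt = SGD(model, config.learning_rate, config.momentum)
        step = 0
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(f_tr))
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = head.forward(f_tr[idx], retain=True)
                loss, g = cross_entropy_with_logits(logits, y_tr[idx])
                head.zero_grad()
                head.backward(g)
                opt.step()
                step += 1
                if step % config.validation_frequency == 0:
                    acc = float((head.forward(f_va).argmax(1) == y_va).mean())
                    history.append({"step": step, "epoch": epoch,
                                    "train_loss": loss, "val_accuracy": acc})
        acc = float((head.forward(f_va).argmax(1) == y_va).mean())
        history.append({"step": step, "epoch": config.max_epochs - 1,
                        "train_loss": history[-1]["train_loss"] if history else None,
                        "val_accuracy": acc})
        w = head.params["W"]
        head.params["b"] = head.params["b"] - (mu / sd) @ w
        head.params["W"] = (w / sd[:, None]).astype(np.float32)
        return model, history

    # full fine-tune
    opt = SGD(model, config.learning_rate, config.momentum)
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = preprocess([x_tr[i] for i in idx], spec)
            acts = model.forward(batch, capture={spec.logits_node}, retain=True)
            loss, g = cross_entropy_with_logits(acts[spec.logits_node], y_tr[idx])
            model.zero_grad()
            model.backward({spec.logits_node: g})
            opt.step()
            step += 1
            if step % config.validation_frequency == 0:
                acc = _accuracy(model, spec, x_va, y_va)
                history.append({"step": step, "epoch": epoch,
                                "train_loss": loss, "val_accuracy": acc})
    history.append({"step": step, "epoch": config.max_epochs - 1,
                    "train_loss": history[-1]["train_loss"] if history else None,
                    "val_accuracy": _accuracy(model, spec, x_va, y_va)})
    return model, history


def _accuracy(model, spec, images, labels):
    probs = predict_proba(model, spec, images)
    return float((probs.argmax(1) == np.asarray(labels)).mean())
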