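"""End-to-end pipeline: synth -> segment -> augment/split -> extract -> fuse
-> classify -> evaluate -> analyze.

Configuration is a flat YAML file with one block per stage; unknown keys
are rejected so typos fail loudly. Every stage error is re-raised tagged
with the stage name. A run writes a self-contained directory: config
snapshot, manifests, metrics JSON, confusion heatmap, embedding CSV and
dendrogram, so that re-running the snapshot reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augmentation as aug
from . import evaluation as ev
from . import fusion as fu
from . import segmentation as seg
from . import synthetic as syn
from .analysis import build_cluster_tree, tsne_embed
from .backbones import TrainConfig, build_backbone, extract_features, finetune
from .errors import ConfigError, PhenofuseError
from .manifest import new_manifest, write_manifest

log = logging.getLogger(__name__)


def _from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown config keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class SynthBlock:
    K: int = 8
    per_class_scans: int = 4
    objects_per_scan: int = 8
    n_sibling_pairs: int = 1
    complementarity: float = 0.5
    sibling_delta: float = 0.01
    canvas: tuple[int, int] = (768, 1024)


@dataclass
class SegmentationBlock:
    method: str = "otsu"
    threshold: float | None = None
    min_area_px: int = 64
    connectivity: int = 8
    drop_border_touching: bool = False
    canvas_size: int = 300
    overflow: str = "rescale"


@dataclass
class AugmentationBlock:
    enabled: bool = True
    target_count: int = 40
    mode: str = "split_before_augment"
    ops: tuple[str, ...] = aug.ALL_OPS
    rotate_angles_deg: tuple[int, ...] = (90, 180, 270)
    shift_max_fraction: float = 0.1


@dataclass
class BackboneBlock:
    name: str = "tiny"
    weights: str = "random"
    layer: str = "pool"


@dataclass
class TrainBlock:
    enabled: bool = False
    batch_size: int = 32
    learning_rate: float = 0.0003
    validation_frequency: int = 64
    max_epochs: int = 5
    freeze_policy: str = "freeze_all_conv"


@dataclass
class FusionBlock:
    strategy: str = "round_robin"
    pairs_per_class: int | None = None
    kernel: str = "linear"
    C: float = 1.0


@dataclass
class AnalysisBlock:
    enabled: bool = True
    tsne_dims: int = 2
    perplexity: float = 30.0
    tree_via_3d: bool = False
    tree_linkage: str = "ward"
    gradcam: bool = False
    gradcam_layer: str = "conv3_relu"


@dataclass
class PipelineConfig:
    rng_seed: int = 0
    out_root: str = "runs"
    split_ratios: tuple[int, int, int] = (8, 1, 1)
    se_convention: str = "sample"
    synth: SynthBlock = field(default_factory=SynthBlock)
    segmentation: SegmentationBlock = field(default_factory=SegmentationBlock)
    augmentation: AugmentationBlock = field(default_factory=AugmentationBlock)
    backbone: BackboneBlock = field(default_factory=BackboneBlock)
    train: TrainBlock = field(default_factory=TrainBlock)
    fusion: FusionBlock = field(default_factory=FusionBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        blocks = {"synth": SynthBlock, "segmentation": SegmentationBlock,
                  "augmentation": AugmentationBlock, "backbone": BackboneBlock,
                  "train": TrainBlock, "fusion": FusionBlock, "analysis": AnalysisBlock}
        kwargs = {}
        for key, bcls in blocks.items():
            if key in data:
                kwargs[key] = _from_dict(bcls, data.pop(key) or {}, key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"config: unknown top-level keys {sorted(unknown)}")
        for k in ("split_ratios",):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PhenofuseError as e:
                raise type(e)(f"stage[{name}]: {e}") from e
        return wrapper
    return deco


def _load_images(paths):
    import imageio.v3 as iio
    return [iio.imread(p) for p in paths]


def run_pipeline(config: PipelineConfig, run_dir=None) -> dict:
    """Execute the full workflow; return the run report (also written as JSON)."""
    import imageio.v3 as iio

    seed = int(config.rng_seed)
    run_dir = Path(run_dir) if run_dir else Path(config.out_root) / f"run_seed{seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    # ---- synth -----------------------------------------------------------
    @_stage("synth")
    def do_synth():
        log.info("stage=synth seed=%d K=%d", seed, config.synth.K)
        return syn.generate_dataset(
            K=config.synth.K, per_class_scans=config.synth.per_class_scans,
            objects_per_scan=config.synth.objects_per_scan,
            out_dir=run_dir / "scans", rng_seed=seed,
            n_sibling_pairs=config.synth.n_sibling_pairs,
            complementarity=config.synth.complementarity,
            sibling_delta=config.synth.sibling_delta,
            canvas=tuple(config.synth.canvas))
    scan_manifest, ground_truth = do_synth()

    # ---- segment ---------------------------------------------------------
    @_stage("segment")
    def do_segment():
        log.info("stage=segment seed=%d scans=%d", seed, len(scan_manifest))
        params = seg.SegmentationParams(
            method=config.segmentation.method, threshold=config.segmentation.threshold,
            min_area_px=config.segmentation.min_area_px,
            connectivity=config.segmentation.connectivity,
            drop_border_touching=config.segmentation.drop_border_touching,
            canvas_size=config.segmentation.canvas_size,
            overflow=config.segmentation.overflow)
        rows = []
        for _, r in scan_manifest.iterrows():
            scan = seg.ScanImage(pixels=iio.imread(r["path"]), organ=r["organ"],
                                 class_label=r["class"], scan_id=r["scan_id"])
            rows += seg.segment_scan_to_dir(scan, run_dir / "objects", params)
        return new_manifest(rows)
    manifest = do_segment()

    # ---- augment / split -------------------------------------------------
    @_stage("augment")
    def do_augment():
        if config.augmentation.enabled:
            policy = aug.AugmentationPolicy(
                ops=tuple(config.augmentation.ops),
                rotate_angles_deg=tuple(config.augmentation.rotate_angles_deg),
                shift_max_fraction=config.augmentation.shift_max_fraction,
                rng_seed=seed)
            log.info("stage=augment seed=%d mode=%s target=%d",
                     seed, config.augmentation.mode, config.augmentation.target_count)
            return aug.augment_dataset(manifest, config.augmentation.target_count,
                                       policy, mode=config.augmentation.mode,
                                       ratios=config.split_ratios, rng_seed=seed)
        log.info("stage=split seed=%d", seed)
        return aug.split_manifest(manifest, ratios=config.split_ratios, rng_seed=seed)
    manifest = do_augment()
    write_manifest(manifest, run_dir / "manifest.csv")

    # ---- per-organ backbones + features ---------------------------------
    organs = {"pod": manifest[manifest["organ"] == "pod"],
              "seed": manifest[manifest["organ"] == "seed"]}
    n_classes = manifest["class"].nunique()
    feats, models = {}, {}

    @_stage("extract")
    def do_extract(organ, organ_manifest, organ_offset):
        log.info("stage=extract seed=%d organ=%s rows=%d", seed, organ, len(organ_manifest))
        model, spec = build_backbone(config.backbone.name, n_classes,
                                     weights=config.backbone.weights,
                                     rng_seed=seed + organ_offset)
        if config.train.enabled:
            tr = organ_manifest[organ_manifest["split"] == "train"]
            va = organ_manifest[organ_manifest["split"] == "val"]
            labels = sorted(organ_manifest["class"].unique())
            lab_idx = {c: i for i, c in enumerate(labels)}
            tcfg = TrainConfig(batch_size=config.train.batch_size,
                               learning_rate=config.train.learning_rate,
                               validation_frequency=config.train.validation_frequency,
                               max_epochs=config.train.max_epochs,
                               freeze_policy=config.train.freeze_policy,
                               rng_seed=seed + organ_offset)
            finetune(model, spec,
                     (_load_images(tr["path"]), [lab_idx[c] for c in tr["class"]]),
                     (_load_images(va["path"]), [lab_idx[c] for c in va["class"]]),
                     tcfg)
        fm = extract_features(model, spec, config.backbone.layer,
                              _load_images(organ_manifest["path"]),
                              row_ids=organ_manifest["path"].tolist())
        return (model, spec), fm

    for off, (organ, om) in enumerate(organs.items(), start=1):
        if om.empty:
            raise ConfigError(f"stage[extract]: no data for organ {organ!r}")
        models[organ], feats[organ] = do_extract(organ, om, off)

    # ---- fuse + classify -------------------------------------------------
    @_stage("fuse")
    def do_fuse(split):
        pairing = fu.make_pairs(organs["pod"], organs["seed"], split,
                                strategy=config.fusion.strategy,
                                pairs_per_class=config.fusion.pairs_per_class,
                                rng_seed=seed)
        return fu.fuse(feats["pod"], feats["seed"], pairing)
    fused = {split: do_fuse(split) for split in ("train", "val", "test")}

    @_stage("classify")
    def do_classify():
        log.info("stage=classify seed=%d kernel=%s", seed, config.fusion.kernel)
        out = {}
        blocks = {"fused": slice(None),
                  "pod_only": slice(0, fused["train"].d_pod),
                  "seed_only": slice(fused["train"].d_pod, None)}
        for name, sl in blocks.items():
            tr = fu.FusedPairSet(values=fused["train"].values[:, sl],
                                 labels=fused["train"].labels,
                                 pairing=fused["train"].pairing)
            clf = fu.train_classifier(tr, kernel=config.fusion.kernel, C=config.fusion.C)
            out[name] = {"model": clf}
            for split in ("val", "test"):
                pred = fu.predict(clf, fused[split].values[:, sl])
                out[name][split] = (fused[split].labels, pred)
        return out
    clf_results = do_classify()

    # ---- evaluate --------------------------------------------------------
    @_stage("evaluate")
    def do_evaluate():
        classes = sorted(manifest["class"].unique())
        report = {}
        for name, res in clf_results.items():
            report[name] = {}
            for split in ("val", "test"):
                true, pred = res[split]
                cm = ev.confusion(true, pred, classes)
                metrics = ev.precision_recall_f1(cm)
                report[name][split] = {"accuracy": metrics.accuracy, **metrics.as_dict()}
                if name == "fused" and split == "test":
                    ev.plot_confusion(cm, run_dir / "confusion_test.png",
                                      title="fused test")
                    np.savetxt(run_dir / "confusion_test.csv", cm.counts,
                               fmt="%d", delimiter=",",
                               header=",".join(classes), comments="")
        return report
    report = {"metrics": do_evaluate(), "rng_seed": seed,
              "n_classes": n_classes,
              "sibling_pairs": ground_truth.get("sibling_pairs", []),
              "complementary_pairs": ground_truth.get("complementary_pairs", [])}

    # ---- analyze ---------------------------------------------------------
    if config.analysis.enabled:
        @_stage("analyze")
        def do_analyze():
            log.info("stage=analyze seed=%d", seed)
            test = fused["test"]
            n = test.values.shape[0]
            perp = min(config.analysis.perplexity, max(0.5, (n - 1) / 3.5))
            emb = tsne_embed(test.values, dims=config.analysis.tsne_dims,
                             perplexity=perp, rng_seed=seed, source="fused/test")
            import pandas as pd
            cols = ["x", "y", "z"][:config.analysis.tsne_dims]
            df = pd.DataFrame(emb.coords, columns=cols)
            df["class"] = test.labels
            df.to_csv(run_dir / "tsne_test.csv", index=False)

            tr = fused["train"]
            labels = np.asarray(tr.labels)
            cls = sorted(set(labels))
            cent = np.vstack([tr.values[labels == c].mean(axis=0) for c in cls])
            tree = build_cluster_tree(cent, cls, via_3d=config.analysis.tree_via_3d,
                                      linkage=config.analysis.tree_linkage,
                                      rng_seed=seed)
            (run_dir / "cluster_tree.nwk").write_text(tree.to_newick() + "\n")
            return {"tsne_rows": int(n), "first_merge": list(tree.first_merge())}
        report["analysis"] = do_analyze()

    with open(run_dir / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
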