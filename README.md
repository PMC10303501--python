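# phenofuse

Dual-organ image feature fusion for identifying near-isogenic plant lines.

## The problem

Mutation breeding produces panels of lines that are genetically — and
visually — almost identical. Classifying such lines from seed images
alone (or pod images alone) hits a ceiling: some line pairs differ only
in their pods, others only in their seeds. `phenofuse` implements the
dual-branch recipe for this problem: scan pods and seeds of each line on
a flat-bed scanner, segment every scan into single-object images pasted
at true scale on a 300×300 black canvas, extract a deep feature vector
per organ image from a named CNN layer (e.g. a ResNet50 global average
pool, 1×2048), concatenate a pod vector and a seed vector of the same
line into one fused vector (1×4096), and classify fused vectors with a
one-vs-one SVM. Per-class precision/recall/F1, confusion matrices with
columns as true classes, Grad-CAM heatmaps, t-SNE embeddings and a
class-level dendrogram complete the workflow.

Because real line panels are rarely deposited, the package ships a
first-class synthetic generator that renders paired pod/seed scans for K
classes with exact ground truth and two controllable confusability
structures: *sibling pairs* (near-duplicate phenotypes in both organs)
and *complementary pairs* (identical in one organ, separable in the
other). Every pipeline stage and every headline claim is tested against
it; see `docs/methods.md` for what the generator does and does not
emulate.

The CNN backbones (AlexNet, GoogLeNet, ResNet18, ResNet50, and a small
`tiny` model) run on a self-contained NumPy engine with named feature
layers and reverse-mode gradients; weights are seeded-random (there is no
bundled pretrained source), which preserves every dimensional contract
and, with a trained head or the downstream SVM, is sufficient for the
package's studies.

## Worked example

Run the full synthetic study from the command line:

```bash
phenofuse run-all --seed 1 --out runs
```

which generates scans, segments them, splits 8:1:1, extracts tiny-backbone
features per organ, fuses and classifies, and prints:

```json
{
  "fused_test_accuracy": 0.9166666666666666,
  "pod_only": 0.875,
  "seed_only": 0.75
}
```

With the default demo config (8 classes including one near-duplicate
sibling pair and two organ-complementary pairs), the fused classifier
reaches ~92% test accuracy while each single-organ branch is capped —
the seed branch cannot separate the class pair whose seeds are
identical, and both branches stumble on the sibling pair. The run
directory (`runs/run_seed1/`) contains the config
snapshot, the object manifest, `metrics.json` with per-class P/R/F1, a
confusion-matrix heatmap, the t-SNE embedding CSV and the class
dendrogram in Newick format.

The same pipeline is available as a library:

```python
from phenofuse import PipelineConfig, run_pipeline

cfg = PipelineConfig(rng_seed=1)
cfg.synth.K = 8
cfg.synth.complementarity = 0.5
report = run_pipeline(cfg)
print(report["metrics"]["fused"]["test"]["accuracy"])
```

Individual stages (`phenofuse synth`, `segment`, `augment`, `split`,
`extract`) operate on manifest CSVs so intermediate state is inspectable.

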