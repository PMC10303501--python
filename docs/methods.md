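# Methods

## Problem and approach

Near-isogenic plant lines (e.g. mutant lines derived from a single
irradiated cultivar) are hard to tell apart from any single organ: two
lines may have indistinguishable seeds but distinct pods, or vice versa.
`phenofuse` implements a dual-branch pipeline that classifies lines from
*paired* organ images: flat-bed scans of pods and seeds are segmented into
single-object images, each organ's images pass through its own CNN branch,
features from a named layer are extracted per organ, a pod vector and a
seed vector of the same class are concatenated, and a one-vs-one SVM
classifies the fused vector. Downstream analysis (Grad-CAM, t-SNE, a class
dendrogram) inspects what the features encode and which lines are close.

## Segmentation and canvas normalization

Scans contain many loose objects of one line on black (the scanner lid is
left open). Processing: BT.601 grayscale -> threshold (Otsu by default;
a fixed threshold is available for reproducibility studies) -> connected
components (8-connectivity, row-major ordering by bounding-box corner,
minimum area 64 px) -> each component pasted, centered, onto a square
black canvas (default 300x300). True object scale is preserved — size is
itself a phenotype — so objects are never upscaled; an object larger than
the canvas is downscaled preserving aspect ratio, with a logged warning
(or rejected, configurable). Every pixel outside the pasted mask is
exactly (0,0,0). Bounding boxes are 0-based, half-open on max edges.
Touching-object separation is out of scope (on real scanners adhered
objects are separated by hand); `drop_border_touching` and the minimum
area are the automated analogues for partial or dust components.

## Balancing and splitting

Groups (class x organ) are balanced to a target count by geometric
augmentation: rotation (multiples of 90°, so the black background stays
exact), integer shifts clamped so content never leaves the canvas
(maximum 10% of the canvas by default), vertical flip and horizontal
mirror. Splits are stratified 8:1:1 per group with floor allocation and
the remainder to train (1000 -> 800/100/100). Two orderings exist:
`augment_then_split` augments first and splits afterwards; the default
`split_before_augment` splits originals first and augments only the
training partition, because near-duplicate augmented copies on both sides
of a split leak information. The augment-first mode is retained so
bookkeeping matches published splits exactly.

## Backbones

Five architectures are registered — AlexNet, GoogLeNet, ResNet18,
ResNet50, and a three-conv-block `tiny` model (64x64 input) for fast
experiments. They are implemented in a small NumPy engine (`phenofuse.nn`):
im2col + BLAS convolutions, NHWC layout, float32, reverse-mode gradients
for every layer. Each backbone declares three feature layers with exact
flattened widths (row-major H,W,C), verified by forward passes:

| backbone  | interior layer                | pool layer            | softmax |
|-----------|-------------------------------|-----------------------|---------|
| alexnet   | relu7 (4096)                  | — (relu7 is the fusion layer) | prob (K) |
| googlenet | inception_5b-output (50176)   | pool5-7x7_s1 (1024)   | prob (K) |
| resnet18  | res5b_relu (25088)            | pool5 (512)           | prob (K) |
| resnet50  | activation_48_relu (50176)    | avg_pool (2048)       | fc1000_softmax (K) |
| tiny      | conv3_relu (8192)             | pool (32)             | prob (K) |

Two naming choices deserve a note. `activation_48_relu` is placed at the
last conv4-stage bottleneck's 3x3 ReLU — the layer whose flattened width
is 14·14·256 = 50176, the width conventionally quoted for that layer name;
stage-5 layers of a standard ResNet50 are 7·7·512 or 7·7·2048 and cannot
produce it. AlexNet's `fc8` is a retrained head, so its width is the class
count, not the ImageNet 4096; `relu7` (4096) is the AlexNet fusion layer.

Weights are He-initialized from a seed. There is no bundled pretrained
weight source, so `weights="pretrained"` raises; random backbones serve as
fixed random feature extractors, which combined with head training or the
downstream SVM is sufficient for every property this package tests.
Normalization constants are configurable; the default scales images to
[0, 1] with no centering, which keeps the black canvas background at
exactly zero so zero-bias convolutions are silent off-object.

Fine-tuning (`finetune`) follows the transfer-learning recipe: under the
default `freeze_all_conv` policy only the classification head is trained
(momentum-SGD, batch 32, learning rate 3e-4, validation every 64 steps by
default; the defaults mirror common practice for this task). Head inputs
are z-scored for conditioning and the affine transform is folded back into
the head weights afterwards, so the trained model still consumes raw
backbone features. `freeze_policy="none"` backpropagates through the whole
graph and is practical for the tiny model.

## Fusion and classification

How individual pod images pair with seed images is not biologically
meaningful (objects are scanned loose), so pairing is an explicit,
deterministic step: `round_robin` (default) sorts each organ's images and
cycles the shorter list; seeded `random` and capped exhaustive pairing are
available. Fused row = [pod block | seed block]. Classification is
per-dimension z-scoring fitted on training pairs only, then a one-vs-one
SVM (linear kernel, C = 1 by default — appropriate for high-dimensional
deep features; RBF available). The standardizer can only be fitted through
`train_classifier`, which precludes test-set leakage by construction.

## Evaluation conventions

Confusion matrices store predicted classes in rows and true classes in
columns, so column sums equal per-class test counts. Per class:
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 is defined as 0 with a
warning and the class is flagged. Macro averages are unweighted; micro
averaging is available. Replicate summaries support three conventions:
sample-SD/sqrt(n) (the standard error, default), population-SD/sqrt(n),
and the population SD itself (`population_sd`), the convention that
reproduces the ± values printed in some replicate tables.

## Analysis

*Grad-CAM*: channel activations at a spatial layer weighted by the
spatially averaged gradient of the class logit, summed, rectified,
min-max normalized, bilinearly upsampled to input resolution. When
checking that heat tracks the organ, the object support is dilated by the
feature layer's receptive-field radius before comparison: a conv cell
whose receptive field overlaps the object is legitimately driven by it,
and at a 16x16 map resolution a tight-mask comparison mostly measures
map coarseness. With a fully trained tiny model on synthetic objects,
~75% of heat falls within the receptive-field support of the organ
(~45% inside the tight mask).

*t-SNE*: seeded scikit-learn embedding to 2-D/3-D (perplexity 30 by
default, clamped when few rows are available); deterministic given the
seed and single-threaded execution.

*Clustering tree*: hierarchical agglomeration (Ward on Euclidean by
default) over per-class mean feature vectors, exported as Newick. An
optional `via_3d` mode reduces centroids to 3-D by t-SNE first — the
common way such dendrograms are drawn — but it is off by default because
a t-SNE of only ~8 centroid points is underdetermined and can scramble
nearest pairs; it is reasonable at ~20 classes. A top-down bisecting
2-means tree is provided as an alternative construction, since "K-means
clustering tree" is ambiguous (K-means yields partitions, not trees).

## Synthetic data generator

The generator is the package's study instrument: parametric phenotypes
per class (seeds: rotated ellipses, base RGB, speckle density, hilum
stripe contrast, axis means/sd; pods: curved lobed capsules with length,
curvature, 2-4 lobes, hue, along-pod texture frequency), rendered as
non-overlapping objects with pose jitter on black 768x1024 canvases, with
exact per-object masks and counts as ground truth. Object scale follows
true-scale scanner crops: seeds ~80-130 px across, pods ~140-220 px long
on the 300-px object canvas. Base phenotypes are well separated by
construction (hues evenly spaced, sizes on a shuffled grid).

Two confusability structures mirror what real mutant-line panels show:

* **Sibling pairs** — a class copied from its partner with every
  continuous parameter nudged by a small relative delta (default 0.01) in
  *both* organs. The default delta is calibrated so that siblings are
  genuinely near-indistinguishable to the pipeline (test recalls ~0.5-0.75
  while other classes stay at ~1.0), the behaviour reported for known
  confusable line pairs. A larger delta makes siblings separable; the
  recall-vs-delta monotonicity is itself under test.
* **Complementary pairs** — two classes with *identical* parameters in
  one organ and well-separated parameters in the other (alternating which
  organ is informative). A single-organ classifier cannot exceed 50%
  recall on classes whose organ is identical to a partner's, giving a
  structural ceiling that fusion can beat.

What the generator does *not* emulate: photorealistic texture, lighting
or shadow variation, color calibration drift, touching/overlapping
objects, within-class genetic segregation. Passing the property suites
therefore demonstrates that the pipeline's machinery is correct and that
its claims hold when the assumed signal structure is present — not field
performance on real scanner data.

## Study designs (pre-registered in `phenofuse.experiments`)

* *Fusion gap*: K = 8 classes, complementarity 0.5, no siblings, 6 scans x
  8 objects per class per organ, no augmentation, tiny backbone (random,
  fixed), linear SVM; test accuracy of fused vs pod-only vs seed-only over
  5 seeds. Fusion exceeds the better single organ by >= 5 points
  (typically ~13 points: fused ~100%, single ~86%).
* *Sibling confusability*: K = 8, one sibling pair, 8 scans x 8 objects;
  per-seed checks that the strictly lowest per-class recall is a sibling
  and that the class dendrogram's first merge is the sibling pair
  (>= 4 of 5 seeds each).
* *Segmentation recovery*: 50 scans, 10 objects each, alternating organs;
  exact object-count recovery (100%).

Problem sizes are the package's chosen desk-scale defaults; all scale
linearly if larger studies are wanted.

## Numerical choices and degenerate inputs

Float32 throughout the network engine; softmax and cross-entropy use the
log-sum-exp guard. Otsu on a constant image returns all-background rather
than failing. Max-pool padding uses -inf so padding never wins; tied
maxima route gradient to the first window position encountering them.
Empty groups, single-class training sets, too-few t-SNE rows, unknown
layers/backbones/keys all raise typed errors (`DataError`, `ConfigError`,
...), and the pipeline driver re-tags them with the failing stage.

## Known limitations

The big backbones are forward-verified with random weights; no claim is
made about their trained ImageNet behaviour. Grad-CAM on a linear head
over pooled features has spatially uniform gradients, so its maps reduce
to a fixed channel combination; full fine-tuning (tiny model) gives more
meaningful maps. The bisecting-k-means tree's heights are within-cluster
dispersions and are not cophenetic distances. The synthetic generator's
confusability knobs are low-dimensional stand-ins for genetic similarity.
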