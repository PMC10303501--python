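"""Synthetic paired pod/seed scan generator with exact ground truth.

Real near-isogenic line datasets are rarely deposited, so every pipeline
stage here is exercised on generated scanner images that emulate their key
statistical structure:

* ``K`` classes ("lines") with parametric phenotypes — seeds are speckled
  ellipses with a hilum stripe, pods are curved multi-lobed capsules —
  rendered on a black background like an open-lid flat-bed scan;
* *sibling pairs*: classes whose phenotypes differ only by a small
  parameter delta in both organs, emulating mutant-line pairs that are
  nearly indistinguishable;
* *complementary pairs*: classes identical in one organ and well separated
  in the other, so that single-organ classifiers hit a ceiling that
  pod+seed fusion can beat — the property the dual-branch design targets.

Shapes are parametric rather than learned, which keeps the generator
dependency-free and the per-object masks exact.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import CapacityError, ConfigError
from .manifest import new_manifest
from .segmentation import ScanImage

DEFAULT_SCAN_CANVAS = (768, 1024)


# --------------------------------------------------------------------------
# phenotypes

@dataclass
class SeedParams:
    axis_major: float          # mean semi-axis, px
    axis_minor: float
    axis_sd: float
    rgb: tuple[int, int, int]
    speckle_density: float     # fraction of object pixels darkened
    hilum_contrast: float      # 0..1 relative darkening of the hilum stripe


@dataclass
class PodParams:
    length: float              # mean pod length, px
    length_sd: float
    curvature: float           # bow height as a fraction of length
    lobes: int                 # 2..4 seed chambers
    rgb: tuple[int, int, int]
    texture_freq: float        # brightness cycles along the pod


@dataclass
class ClassPhenotype:
    label: str
    seed: SeedParams
    pod: PodParams
    informative_organ: str = "both"   # organ that separates this class from its partner
    partner: str | None = None
    relation: str = "none"            # none | sibling | complementary

    def __post_init__(self):
        for v in (self.seed.axis_major, self.seed.axis_minor, self.pod.length):
            if v <= 0:
                raise ConfigError("phenotype axes/length must be positive")
        if self.seed.axis_sd < 0 or self.pod.length_sd < 0:
            raise ConfigError("phenotype sd must be >= 0")
        for c in (*self.seed.rgb, *self.pod.rgb):
            if not 0 <= c <= 255:
                raise ConfigError("phenotype RGB out of [0, 255]")


def seed_param_vector(p: ClassPhenotype) -> np.ndarray:
    """Seed parameters on comparable scales (for phenotype distance audits)."""
    s = p.seed
    return np.array([s.axis_major, s.axis_minor, *(np.array(s.rgb) / 8.0),
                     s.speckle_density * 200, s.hilum_contrast * 30])


def pod_param_vector(p: ClassPhenotype) -> np.ndarray:
    q = p.pod
    return np.array([q.length / 4.0, q.curvature * 100, q.lobes * 10.0,
                     *(np.array(q.rgb) / 8.0), q.texture_freq * 5])


def _hsv_rgb(h, s, v) -> tuple[int, int, int]:
    r, g, b = colorsys.hsv_to_rgb(h % 1.0, s, v)
    return tuple(int(round(60 + c * 180)) for c in (r, g, b))


def _perturb(pheno: ClassPhenotype, delta: float, rng: np.random.Generator) -> ClassPhenotype:
    """Copy a phenotype with every continuous parameter nudged by ~delta (relative)."""
    def nudge(x, lo=None, hi=None):
        y = x * (1.0 + delta * rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.0))
        if lo is not None:
            y = max(lo, y)
        if hi is not None:
            y = min(hi, y)
        return y

    def nudge_rgb(rgb):
        shift = rng.choice([-1.0, 1.0], size=3) * delta * 255 * rng.uniform(0.5, 1.0, size=3)
        return tuple(int(np.clip(round(c + s), 0, 255)) for c, s in zip(rgb, shift))

    s, q = pheno.seed, pheno.pod
    return ClassPhenotype(
        label=pheno.label,
        seed=SeedParams(nudge(s.axis_major, 6), nudge(s.axis_minor, 4), s.axis_sd,
                        nudge_rgb(s.rgb), max(0.0, nudge(s.speckle_density + 1e-3)),
                        min(1.0, max(0.0, nudge(s.hilum_contrast)))),
        pod=PodParams(nudge(q.length, 40), q.length_sd,
                      min(0.4, max(0.02, nudge(q.curvature))), q.lobes,
                      nudge_rgb(q.rgb), max(1.0, nudge(q.texture_freq))),
    )


def generate_phenotypes(
    K: int,
    n_sibling_pairs: int = 0,
    complementarity: float = 0.0,
    rng_seed: int = 0,
    sibling_delta: float = 0.01,
) -> tuple[list[ClassPhenotype], dict]:
    """Draw ``K`` class phenotypes with configured confusability structure.

    The first ``2 * n_sibling_pairs`` classes form sibling pairs (small
    ``sibling_delta`` difference in both organs). Of the remaining classes,
    a fraction ``complementarity`` of consecutive pairs is made
    complementary: identical parameters in one organ, well separated in the
    other, alternating which organ carries the signal.

    Returns the phenotype list and a ground-truth header recording pair
    structure and the seed.
    """
    if K < 2:
        raise ConfigError("need at least 2 classes")
    if not 0 <= complementarity <= 1:
        raise ConfigError("complementarity must be in [0, 1]")
    if 2 * n_sibling_pairs > K:
        raise ConfigError(f"{n_sibling_pairs} sibling pairs do not fit in {K} classes")
    rng = np.random.default_rng(rng_seed)
    labels = [f"line{i + 1:02d}" for i in range(K)]

    # Well-separated bases: hues evenly spaced, sizes on a shuffled grid so
    # no two classes collide in either organ by construction.
    seed_hues = (np.arange(K) / K + rng.uniform(0, 1 / (2 * K))) % 1.0
    pod_hue_order = rng.permutation(K)
    # true-scale scanner objects: seeds ~80-130 px across, pods ~140-220 px long
    seed_sizes = 40 + 22 * rng.permutation(K) / max(K - 1, 1)
    pod_lengths = 140 + 80 * rng.permutation(K) / max(K - 1, 1)

    phenos: list[ClassPhenotype] = []
    for i, lab in enumerate(labels):
        a = float(seed_sizes[i])
        phenos.append(ClassPhenotype(
            label=lab,
            seed=SeedParams(
                axis_major=a,
                axis_minor=a * rng.uniform(0.62, 0.82),
                axis_sd=1.0,
                rgb=_hsv_rgb(seed_hues[i], rng.uniform(0.5, 0.85), rng.uniform(0.55, 0.85)),
                speckle_density=rng.uniform(0.0, 0.03),
                hilum_contrast=rng.uniform(0.2, 0.6),
            ),
            pod=PodParams(
                length=float(pod_lengths[i]),
                length_sd=4.0,
                curvature=rng.uniform(0.05, 0.25),
                lobes=int(rng.integers(2, 5)),
                rgb=_hsv_rgb(0.07 + 0.28 * pod_hue_order[i] / max(K - 1, 1),
                             rng.uniform(0.45, 0.8), rng.uniform(0.5, 0.8)),
                texture_freq=rng.uniform(2.0, 6.0),
            ),
        ))

    sibling_pairs = []
    for k in range(n_sibling_pairs):
        i, j = 2 * k, 2 * k + 1
        phenos[j] = _perturb(phenos[i], sibling_delta, rng)
        phenos[j].label = labels[j]
        for a_, b_ in ((i, j), (j, i)):
            phenos[a_].partner = labels[b_]
            phenos[a_].relation = "sibling"
        sibling_pairs.append((labels[i], labels[j]))

    rest = list(range(2 * n_sibling_pairs, K))
    free_pairs = [(rest[t], rest[t + 1]) for t in range(0, len(rest) - 1, 2)]
    n_comp = int(round(complementarity * len(free_pairs)))
    complementary_pairs = []
    for t in range(n_comp):
        i, j = free_pairs[t]
        informative = "seed" if t % 2 == 0 else "pod"
        if informative == "seed":       # pods identical -> only seeds separate the pair
            phenos[j].pod = PodParams(**asdict(phenos[i].pod))
        else:
            phenos[j].seed = SeedParams(**asdict(phenos[i].seed))
        for a_, b_ in ((i, j), (j, i)):
            phenos[a_].partner = labels[b_]
            phenos[a_].relation = "complementary"
            phenos[a_].informative_organ = informative
        complementary_pairs.append((labels[i], labels[j], informative))

    header = {
        "rng_seed": int(rng_seed),
        "K": K,
        "sibling_delta": sibling_delta,
        "sibling_pairs": sibling_pairs,
        "complementary_pairs": complementary_pairs,
        "phenotypes": [asdict(p) for p in phenos],
    }
    return phenos, header


# --------------------------------------------------------------------------
# rendering

def _render_seed(p: SeedParams, rng: np.random.Generator):
    a = float(np.clip(rng.normal(p.axis_major, p.axis_sd), 6, 90))
    b = float(np.clip(rng.normal(p.axis_minor, p.axis_sd), 5, a))
    theta = rng.uniform(0, np.pi)
    half = int(np.ceil(max(a, b))) + 2
    size = 2 * half + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_ellipse(half, half, a, b, shape=mask.shape, rotation=theta)
    mask[rr, cc] = True

    patch = np.zeros((size, size, 3), dtype=np.float64)
    patch[mask] = np.array(p.rgb) + rng.normal(0, 5, size=(int(mask.sum()), 3))

    # hilum: a small dark ellipse at one end of the major axis
    hr = half + 0.62 * a * np.cos(theta)
    hc = half - 0.62 * a * np.sin(theta)
    rr, cc = draw_ellipse(hr, hc, 0.3 * a, 0.18 * b + 1, shape=mask.shape, rotation=theta)
    hil = np.zeros_like(mask)
    hil[rr, cc] = True
    hil &= mask
    patch[hil] *= (1.0 - p.hilum_contrast)

    n_speck = int(p.speckle_density * mask.sum())
    if n_speck:
        obj = np.flatnonzero(mask)
        pick = rng.choice(obj, size=min(n_speck, obj.size), replace=False)
        flat = patch.reshape(-1, 3)
        flat[pick] *= 0.5
    return np.clip(patch, 0, 255).astype(np.uint8), mask


def _render_pod(p: PodParams, rng: np.random.Generator):
    L = float(np.clip(rng.normal(p.length, p.length_sd), 40, 280))
    theta = rng.uniform(0, np.pi)
    r_base = max(6.0, L / 7.0)
    bow = p.curvature * L

    # Spine sampled densely; pod = union of disks whose radius bulges at each
    # lobe and pinches between lobes (stays connected by construction).
    ts = np.linspace(0.04, 0.96, max(24, int(L / 2)))
    xs = (ts - 0.5) * L
    ys = bow * np.sin(np.pi * ts) - bow * 2 / np.pi   # centered bow
    ct, st = np.cos(theta), np.sin(theta)
    rs = xs * st + ys * ct
    cs = xs * ct - ys * st
    taper = np.sqrt(np.clip(4 * ts * (1 - ts), 0.08, 1.0))   # rounded ends
    radii = r_base * taper * (0.72 + 0.38 * np.abs(np.sin(np.pi * p.lobes * ts)))

    pad = int(np.ceil(radii.max())) + 3
    r0, c0 = rs.min() - pad, cs.min() - pad
    size_r = int(np.ceil(rs.max() + pad - r0)) + 1
    size_c = int(np.ceil(cs.max() + pad - c0)) + 1
    mask = np.zeros((size_r, size_c), dtype=bool)
    for k in range(ts.size):
        rr, cc = draw_ellipse(rs[k] - r0, cs[k] - c0, radii[k], radii[k],
                              shape=mask.shape)
        mask[rr, cc] = True

    patch = np.zeros((size_r, size_c, 3), dtype=np.float64)
    obj_r, obj_c = np.nonzero(mask)
    # brightness modulated along the spine: cos(2*pi*f*t), t in [0,1]
    t = ((obj_r + r0) * st + (obj_c + c0) * ct) / L + 0.5
    mod = 1.0 + 0.16 * np.cos(2 * np.pi * p.texture_freq * t)
    patch[obj_r, obj_c] = (np.array(p.rgb)[None, :] * mod[:, None]
                           + rng.normal(0, 5, size=(obj_r.size, 3)))
    return np.clip(patch, 0, 255).astype(np.uint8), mask


@dataclass
class ScanTruth:
    """Exact per-scan ground truth: object count, bboxes, local masks."""

    count: int
    bboxes: list[tuple[int, int, int, int]]
    masks: list[np.ndarray] = field(repr=False)   # local masks matching each bbox
    class_label: str = ""
    organ: str = ""

    def full_mask(self, i: int, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bboxes[i]
        out[r0:r1, c0:c1] = self.masks[i]
        return out


def render_scan(
    phenotype: ClassPhenotype,
    organ: str,
    n_objects: int,
    canvas: tuple[int, int] = DEFAULT_SCAN_CANVAS,
    rng_seed: int = 0,
    scan_id: str = "scan0",
    min_gap: int = 4,
    max_attempts_per_object: int = 400,
) -> tuple[ScanImage, ScanTruth]:
    """Render one scan: ``n_objects`` non-touching objects on black.

    Placement is rejection sampling against an occupancy map with a
    ``min_gap`` pixel margin; exceeding the attempt cap raises
    :class:`CapacityError` (the canvas is too full for the requested count).
    """
    if organ not in ("pod", "seed"):
        raise ConfigError(f"organ must be 'pod' or 'seed', got {organ!r}")
    rng = np.random.default_rng(rng_seed)
    H, W = canvas
    pixels = np.zeros((H, W, 3), dtype=np.uint8)
    occupancy = np.zeros((H, W), dtype=bool)
    truth = ScanTruth(count=0, bboxes=[], masks=[],
                      class_label=phenotype.label, organ=organ)
    render = _render_seed if organ == "seed" else _render_pod
    params = phenotype.seed if organ == "seed" else phenotype.pod

    for _ in range(n_objects):
        placed = False
        patch, mask = render(params, rng)
        for _attempt in range(max_attempts_per_object):
            ph, pw = mask.shape
            # redraw (new size jitter / pose) if the patch cannot fit the
            # canvas at all, or periodically when free space is fragmented
            if (ph + 2 * min_gap >= H or pw + 2 * min_gap >= W
                    or (_attempt > 0 and _attempt % 40 == 0)):
                patch, mask = render(params, rng)
                continue
            top = int(rng.integers(min_gap, H - ph - min_gap))
            left = int(rng.integers(min_gap, W - pw - min_gap))
            window = occupancy[max(0, top - min_gap):top + ph + min_gap,
                               max(0, left - min_gap):left + pw + min_gap]
            if window.any():
                continue
            pixels[top:top + ph, left:left + pw][mask] = patch[mask]
            occupancy[top:top + ph, left:left + pw] |= mask
            # tighten bbox to the mask itself
            rs, cs = np.nonzero(mask)
            r0, r1 = rs.min(), rs.max() + 1
            c0, c1 = cs.min(), cs.max() + 1
            truth.bboxes.append((top + r0, left + c0, top + r1, left + c1))
            truth.masks.append(mask[r0:r1, c0:c1].copy())
            truth.count += 1
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place object {truth.count + 1}/{n_objects} on {canvas} canvas "
                f"after {max_attempts_per_object} attempts"
            )
    scan = ScanImage(pixels=pixels, organ=organ, class_label=phenotype.label,
                     scan_id=scan_id)
    return scan, truth


# --------------------------------------------------------------------------
# dataset composition

def generate_dataset(
    K: int,
    per_class_scans: int,
    objects_per_scan: int,
    out_dir,
    rng_seed: int = 0,
    n_sibling_pairs: int = 0,
    complementarity: float = 0.0,
    sibling_delta: float = 0.01,
    canvas: tuple[int, int] = DEFAULT_SCAN_CANVAS,
    organs: tuple[str, ...] = ("pod", "seed"),
    phenotypes: list[ClassPhenotype] | None = None,
):
    """Write a full synthetic scan dataset: PNG scans, manifest, ground truth.

    Returns ``(manifest, ground_truth)`` where manifest rows reference the
    whole-scan images (``object_index = -1``, split unassigned) and the
    ground truth dict records phenotypes, pair structure, and per-scan
    object counts and bboxes.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if phenotypes is None:
        phenotypes, header = generate_phenotypes(
            K, n_sibling_pairs=n_sibling_pairs, complementarity=complementarity,
            rng_seed=rng_seed, sibling_delta=sibling_delta)
    else:
        header = {"rng_seed": int(rng_seed), "K": len(phenotypes),
                  "sibling_pairs": [], "complementary_pairs": [],
                  "phenotypes": [asdict(p) for p in phenotypes]}

    master = np.random.default_rng(rng_seed)
    rows, scans_truth = [], []
    for pheno in phenotypes:
        for organ in organs:
            for s in range(per_class_scans):
                sid = f"{organ}{s:03d}"
                sub_seed = int(master.integers(2 ** 31))
                scan, truth = render_scan(pheno, organ, objects_per_scan,
                                          canvas=canvas, rng_seed=sub_seed, scan_id=sid)
                path = out_dir / f"{pheno.label}_{organ}_{sid}.png"
                iio.imwrite(path, scan.pixels)
                rows.append({
                    "path": str(path), "class": pheno.label, "organ": organ,
                    "scan_id": sid, "object_index": -1, "area_px": 0,
                    "split": "unassigned", "is_augmented": False, "source_path": "",
                })
                scans_truth.append({
                    "path": str(path), "class": pheno.label, "organ": organ,
                    "scan_id": sid, "count": truth.count,
                    "bboxes": [list(map(int, b)) for b in truth.bboxes],
                })
    ground_truth = {**header, "scans": scans_truth}
    manifest = new_manifest(rows)
    manifest.to_csv(out_dir / "scan_manifest.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh)
    return manifest, ground_truth
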