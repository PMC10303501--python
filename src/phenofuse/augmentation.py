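"""Class balancing by geometric augmentation, and stratified splitting.

Each (class, organ) group is grown to a target count with rotation, shift,
flip and mirror operations on the canvas-normalized images, then the
manifest is split 8:1:1 into train/validation/test per group.

Two orderings are supported. ``augment_then_split`` augments first and then
splits, so near-duplicates of one source image can land in different
partitions. The default, ``split_before_augment``, splits the original
objects first and augments only the training partition, which removes that
leakage channel; the per-partition targets keep the 8:1:1 proportion of
the overall target count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .manifest import append_rows

ALL_OPS = ("rotate", "shift", "flip_vertical", "mirror_horizontal")


@dataclass
class AugmentationPolicy:
    """Which geometric ops may be sampled, and their parameter ranges."""

    ops: tuple[str, ...] = ALL_OPS
    rotate_angles_deg: tuple[int, ...] = (90, 180, 270)
    shift_max_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if not self.ops:
            raise ConfigError("augmentation policy must enable at least one op")
        unknown = set(self.ops) - set(ALL_OPS)
        if unknown:
            raise ConfigError(f"unknown augmentation ops: {sorted(unknown)}")
        if not 0 <= self.shift_max_fraction <= 0.2:
            raise ConfigError("shift_max_fraction must be in [0, 0.2]")
        if "rotate" in self.ops:
            bad = [a for a in self.rotate_angles_deg if a % 90 != 0]
            if bad:
                raise ConfigError(f"rotate angles must be multiples of 90, got {bad}")


def apply_op(image: np.ndarray, op: str, param) -> np.ndarray:
    """Apply one geometric op to an HxWx3 canvas image.

    Rotation is restricted to multiples of 90 degrees so the black
    background stays exact (no interpolation). Shifts are integer pixel
    offsets clamped by the caller so content never leaves the canvas.
    """
    if op == "rotate":
        return np.ascontiguousarray(np.rot90(image, k=(int(param) // 90) % 4))
    if op == "flip_vertical":
        return np.ascontiguousarray(np.flipud(image))
    if op == "mirror_horizontal":
        return np.ascontiguousarray(np.fliplr(image))
    if op == "shift":
        dr, dc = param
        out = np.zeros_like(image)
        h, w = image.shape[:2]
        src_r = slice(max(0, -dr), min(h, h - dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_r = slice(max(0, dr), max(0, dr) + (src_r.stop - src_r.start))
        dst_c = slice(max(0, dc), max(0, dc) + (src_c.stop - src_c.start))
        out[dst_r, dst_c] = image[src_r, src_c]
        return out
    raise ConfigError(f"unknown op {op!r}")


def _safe_shift_bounds(image: np.ndarray, max_fraction: float):
    """Largest |shift| per axis that keeps all nonzero content on canvas."""
    h, w = image.shape[:2]
    fg = image.any(axis=2) if image.ndim == 3 else image != 0
    if not fg.any():
        return (0, 0, 0, 0)
    rs, cs = np.nonzero(fg)
    cap_r, cap_c = int(max_fraction * h), int(max_fraction * w)
    return (-min(rs.min(), cap_r), min(h - 1 - rs.max(), cap_r),
            -min(cs.min(), cap_c), min(w - 1 - cs.max(), cap_c))


@dataclass
class AugmentedGroup:
    """``images[i]`` for i < n_original are the inputs; the rest are generated.

    ``provenance[j]`` records (source_index, op, param) for generated image j
    (aligned to ``images[n_original + j]``).
    """

    images: list[np.ndarray]
    n_original: int
    provenance: list[tuple[int, str, object]]


def augment_group(images: list[np.ndarray], target_count: int,
                  policy: AugmentationPolicy) -> AugmentedGroup:
    """Grow a group of images to exactly ``target_count``.

    Generated images are produced by a seeded RNG: pick a source uniformly,
    pick an enabled op uniformly, pick its parameter uniformly. Order is
    deterministic given the policy seed.
    """
    if not images:
        raise DataError("cannot augment an empty group")
    if target_count < len(images):
        raise ConfigError(f"target_count {target_count} below group size {len(images)}")
    rng = np.random.default_rng(policy.rng_seed)
    out = list(images)
    provenance: list[tuple[int, str, object]] = []
    while len(out) < target_count:
        src = int(rng.integers(len(images)))
        op = str(rng.choice(policy.ops))
        if op == "rotate":
            param = int(rng.choice(policy.rotate_angles_deg))
        elif op == "shift":
            lo_r, hi_r, lo_c, hi_c = _safe_shift_bounds(images[src], policy.shift_max_fraction)
            param = (int(rng.integers(lo_r, hi_r + 1)), int(rng.integers(lo_c, hi_c + 1)))
        else:
            param = None
        out.append(apply_op(images[src], op, param))
        provenance.append((src, op, param))
    return AugmentedGroup(images=out, n_original=len(images), provenance=provenance)


def split_manifest(manifest: pd.DataFrame, ratios: tuple[int, int, int] = (8, 1, 1),
                   rng_seed: int = 0) -> pd.DataFrame:
    """Stratified train/val/test assignment per (class, organ) group.

    Within each group rows are shuffled with a seeded RNG; val and test get
    ``floor(n * ratio / total)`` rows each and the remainder goes to train,
    so 1000 rows under 8:1:1 gives exactly 800/100/100.
    """
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) == 0:
        raise ConfigError(f"bad split ratios {ratios}")
    total = sum(ratios)
    out = manifest.copy()
    rng = np.random.default_rng(rng_seed)
    for (cls, organ), group in manifest.groupby(["class", "organ"], sort=True):
        n = len(group)
        if n < 3:
            raise DataError(f"group ({cls}, {organ}) has only {n} rows; need >= 3 to split")
        # stable order first so the assignment depends only on content + seed
        idx = group.sort_values("path").index.to_numpy()
        rng.shuffle(idx)
        n_val = n * ratios[1] // total
        n_test = n * ratios[2] // total
        out.loc[idx[:n_val], "split"] = "val"
        out.loc[idx[n_val:n_val + n_test], "split"] = "test"
        out.loc[idx[n_val + n_test:], "split"] = "train"
    return out


def _augment_rows_to_disk(rows: pd.DataFrame, n_new: int, policy: AugmentationPolicy,
                          split: str) -> list[dict]:
    """Generate n_new augmented files from the given original rows."""
    import imageio.v3 as iio

    images = [iio.imread(p) for p in rows["path"]]
    group = augment_group(images, len(images) + n_new, policy)
    new_rows = []
    for j, (src, op, param) in enumerate(group.provenance):
        src_row = rows.iloc[src]
        src_path = Path(src_row["path"])
        out_path = src_path.with_name(f"{src_path.stem}_aug{j:03d}{src_path.suffix}")
        iio.imwrite(out_path, group.images[group.n_original + j])
        new_rows.append({
            "path": str(out_path), "class": src_row["class"], "organ": src_row["organ"],
            "scan_id": src_row["scan_id"], "object_index": src_row["object_index"],
            "area_px": src_row["area_px"], "split": split,
            "is_augmented": True, "source_path": str(src_path),
        })
    return new_rows


def augment_dataset(manifest: pd.DataFrame, target_count: int,
                    policy: AugmentationPolicy, mode: str = "split_before_augment",
                    ratios: tuple[int, int, int] = (8, 1, 1), rng_seed: int = 0,
                    ) -> pd.DataFrame:
    """Balance every (class, organ) group to ``target_count`` and split.

    ``mode="augment_then_split"``: augment all originals to the target, then
    split everything 8:1:1. ``mode="split_before_augment"`` (default):
    split originals first, then augment only the train partition up to
    ``target_count * ratios[0] / sum(ratios)``.
    """
    if mode not in ("augment_then_split", "split_before_augment"):
        raise ConfigError(f"unknown augmentation mode {mode!r}")
    total = sum(ratios)
    out_rows: list[dict] = []
    if mode == "augment_then_split":
        result = manifest.copy()
        for gi, (_, group) in enumerate(manifest.groupby(["class", "organ"], sort=True)):
            n_new = target_count - len(group)
            if n_new < 0:
                raise ConfigError(f"group larger ({len(group)}) than target {target_count}")
            gp = AugmentationPolicy(policy.ops, policy.rotate_angles_deg,
                                    policy.shift_max_fraction, policy.rng_seed + gi)
            out_rows += _augment_rows_to_disk(group, n_new, gp, "unassigned")
        result = append_rows(result, out_rows)
        return split_manifest(result, ratios=ratios, rng_seed=rng_seed)

    result = split_manifest(manifest, ratios=ratios, rng_seed=rng_seed)
    train_target = target_count * ratios[0] // total
    for gi, (_, group) in enumerate(result.groupby(["class", "organ"], sort=True)):
        train_rows = group[group["split"] == "train"]
        n_new = train_target - len(train_rows)
        if n_new <= 0:
            continue
        gp = AugmentationPolicy(policy.ops, policy.rotate_angles_deg,
                                policy.shift_max_fraction, policy.rng_seed + gi)
        out_rows += _augment_rows_to_disk(train_rows, n_new, gp, "train")
    return append_rows(result, out_rows)
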