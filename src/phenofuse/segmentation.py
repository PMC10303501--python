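"""Scanner-image segmentation and canvas normalization.

Flat-bed scans show many seeds or pods of one line on a black background
(the scanner lid is left open). Each scan is converted to grayscale,
binarized, decomposed into connected components, and every component is
pasted — at true pixel scale, centered — onto a fixed-size black canvas.
Keeping the true scale matters: seed and pod size is itself a phenotype,
so objects are never enlarged, and only downscaled when one physically
exceeds the canvas.

Coordinates are 0-based; bounding boxes are half-open on their max edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

from .errors import ConfigError, DataError, FormatError, SizeError

log = logging.getLogger(__name__)

DEFAULT_CANVAS = 300
DEFAULT_MIN_AREA = 64

# ITU-R BT.601 luminance weights — the classic RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class ScanImage:
    """A raw multi-object scanner image of one line and one organ."""

    pixels: np.ndarray  # H x W x 3 uint8
    organ: str
    class_label: str
    scan_id: str

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"scan {self.scan_id!r}: expected HxWx3 RGB, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"scan {self.scan_id!r}: empty raster")
        self.pixels = px.astype(np.uint8, copy=False)


@dataclass
class ObjectROI:
    """One connected foreground component of a scan.

    ``bbox`` is (row_min, col_min, row_max, col_max), half-open on the max
    edges; ``mask_crop`` has shape (row_max - row_min, col_max - col_min).
    """

    bbox: tuple[int, int, int, int]
    area_px: int
    mask_crop: np.ndarray = field(repr=False)

    def __post_init__(self):
        r0, c0, r1, c1 = self.bbox
        if self.area_px <= 0:
            raise DataError("ROI with non-positive area")
        if self.mask_crop.shape != (r1 - r0, c1 - c0):
            raise DataError("ROI mask_crop extent does not match bbox")
        if int(self.mask_crop.sum()) != self.area_px:
            raise DataError("ROI area_px does not equal mask pixel count")


@dataclass
class NormalizedObjectImage:
    """A single object pasted centered on a square black canvas."""

    pixels: np.ndarray  # canvas x canvas x 3 uint8
    mask: np.ndarray    # canvas x canvas bool, the pasted object mask
    source_scan: str
    object_index: int


def to_grayscale(image: ScanImage | np.ndarray) -> np.ndarray:
    """Convert an RGB raster to a float grayscale raster in [0, 255].

    Uses the standard luminance weighting 0.299 R + 0.587 G + 0.114 B.
    """
    px = image.pixels if isinstance(image, ScanImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise FormatError(f"expected HxWx3 RGB raster, got shape {px.shape}")
    return px.astype(np.float64) @ LUMA_WEIGHTS


def binarize(gray: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale raster into a boolean foreground mask.

    Parameters
    ----------
    method
        ``"otsu"`` picks the threshold maximizing between-class variance;
        ``"fixed"`` requires an explicit ``threshold``. In both cases
        foreground is ``gray > threshold``.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise FormatError(f"expected single-channel raster, got shape {gray.shape}")
    if method == "fixed":
        if threshold is None:
            raise ConfigError("binarize(method='fixed') requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0:
            # Constant image: Otsu is undefined; call everything background.
            return np.zeros(gray.shape, dtype=bool)
        t = float(threshold_otsu(gray))
    else:
        raise ConfigError(f"unknown binarization method {method!r}")
    return gray > t


def extract_objects(
    mask: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    drop_border_touching: bool = False,
) -> list[ObjectROI]:
    """Connected-component decomposition of a foreground mask into ROIs.

    ROIs are ordered row-major by bbox top-left corner, which makes the
    object indexing deterministic for a given mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    labelled = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    rois: list[ObjectROI] = []
    h, w = mask.shape
    for region in regionprops(labelled):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        if drop_border_touching and (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
            continue
        crop = labelled[r0:r1, c0:c1] == region.label
        rois.append(ObjectROI(bbox=(r0, c0, r1, c1), area_px=int(region.area), mask_crop=crop))
    rois.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return rois


def normalize_to_canvas(
    image: ScanImage,
    roi: ObjectROI,
    canvas_size: int = DEFAULT_CANVAS,
    overflow: str = "error",
    object_index: int = 0,
) -> NormalizedObjectImage:
    """Paste one segmented object, centered, onto a black square canvas.

    Every pixel outside the object's mask is exactly (0, 0, 0), matching
    the binary-image background; object pixels are copied unchanged from
    the source scan. If the object exceeds the canvas, behaviour depends on
    ``overflow``: ``"error"`` raises, ``"rescale"`` downscales preserving
    aspect ratio (with a logged warning) — objects are never upscaled.
    """
    r0, c0, r1, c1 = roi.bbox
    h, w = image.pixels.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise DataError(f"ROI bbox {roi.bbox} outside scan bounds {(h, w)}")
    patch = image.pixels[r0:r1, c0:c1].copy()
    mask = roi.mask_crop.copy()
    patch[~mask] = 0

    ph, pw = patch.shape[:2]
    if ph > canvas_size or pw > canvas_size:
        if overflow == "error":
            raise SizeError(
                f"object {ph}x{pw} exceeds canvas {canvas_size}; use overflow='rescale'"
            )
        if overflow != "rescale":
            raise ConfigError(f"unknown overflow mode {overflow!r}")
        scale = canvas_size / max(ph, pw)
        nh, nw = max(1, math.floor(ph * scale)), max(1, math.floor(pw * scale))
        log.warning(
            "scan %s object %d: %dx%d exceeds canvas %d, rescaling to %dx%d",
            image.scan_id, object_index, ph, pw, canvas_size, nh, nw,
        )
        patch = (resize(patch, (nh, nw), order=1, preserve_range=True, anti_aliasing=True)
                 .round().astype(np.uint8))
        mask = resize(mask.astype(float), (nh, nw), order=0, preserve_range=True) > 0.5
        patch[~mask] = 0
        ph, pw = nh, nw

    canvas = np.zeros((canvas_size, canvas_size, 3), dtype=np.uint8)
    full_mask = np.zeros((canvas_size, canvas_size), dtype=bool)
    top = (canvas_size - ph) // 2
    left = (canvas_size - pw) // 2
    canvas[top:top + ph, left:left + pw][mask] = patch[mask]
    full_mask[top:top + ph, left:left + pw] = mask
    return NormalizedObjectImage(
        pixels=canvas, mask=full_mask, source_scan=image.scan_id, object_index=object_index
    )


@dataclass
class SegmentationParams:
    method: str = "otsu"
    threshold: float | None = None
    min_area_px: int = DEFAULT_MIN_AREA
    connectivity: int = 8
    drop_border_touching: bool = False
    canvas_size: int = DEFAULT_CANVAS
    overflow: str = "rescale"


def segment_scan(image: ScanImage, params: SegmentationParams | None = None,
                 ) -> list[NormalizedObjectImage]:
    """Full single-scan segmentation: gray -> binary -> ROIs -> canvases."""
    params = params or SegmentationParams()
    gray = to_grayscale(image)
    mask = binarize(gray, method=params.method, threshold=params.threshold)
    rois = extract_objects(
        mask,
        min_area_px=params.min_area_px,
        connectivity=params.connectivity,
        drop_border_touching=params.drop_border_touching,
    )
    return [
        normalize_to_canvas(image, roi, canvas_size=params.canvas_size,
                            overflow=params.overflow, object_index=i)
        for i, roi in enumerate(rois)
    ]


def segment_scan_to_dir(image: ScanImage, out_dir, params: SegmentationParams | None = None,
                        ) -> list[dict]:
    """Segment a scan, write one PNG per object, return manifest rows."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for obj in segment_scan(image, params):
        name = f"{image.class_label}_{image.organ}_{image.scan_id}_{obj.object_index}.png"
        path = out_dir / name
        iio.imwrite(path, obj.pixels)
        rows.append({
            "path": str(path),
            "class": image.class_label,
            "organ": image.organ,
            "scan_id": image.scan_id,
            "object_index": obj.object_index,
            "area_px": int(obj.mask.sum()),
            "split": "unassigned",
            "is_augmented": False,
            "source_path": "",
        })
    return rows
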