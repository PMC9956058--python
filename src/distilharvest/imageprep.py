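"""Preprocessing and augmentation for the defect-detection corpus.

Covers the acquisition pipeline's image conditioning — luminance grayscale,
bimodal-threshold ROI extraction, square resize to the detector raster — and
the two bespoke augmentations used for training: regular white line-segment
occlusion (stripes of width W every G+W pixels, W and G drawn once per call)
and the 4-image mosaic splice.  Augmentations keep every annotation valid
(normalized boxes stay in [0, 1]) and never touch val/test imagery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import filters, measure, morphology

from .errors import ConfigurationError, NoROIError
from .synthcarrot import AnnotatedImage

# standard luminance weights for the weighted-average grayscale
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class OcclusionConfig:
    """Stripe-occlusion parameters: spacing G and width W are drawn uniformly
    from [G_min, G_max] / [W_min, W_max] once per call."""

    g_min: int = 6
    g_max: int = 14
    w_min: int = 2
    w_max: int = 6
    color: tuple[int, int, int] = (255, 255, 255)
    orientation: str = "both"   # horizontal | vertical | both
    seed: int = 0

    def validate(self):
        if not (0 <= self.w_min <= self.w_max):
            raise ConfigurationError("need 0 <= W_min <= W_max")
        if not (0 < self.g_min <= self.g_max):
            raise ConfigurationError("need 0 < G_min <= G_max")
        if self.orientation not in ("horizontal", "vertical", "both"):
            raise ConfigurationError(f"bad orientation {self.orientation!r}")
        return self


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Weighted-average grayscale with the standard luminance weights."""
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    w = np.asarray(GRAY_WEIGHTS)
    gray = pixels.astype(np.float64) @ w
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def extract_roi(gray: np.ndarray):
    """Foreground mask + bounding crop from an automatic bimodal threshold.

    Otsu threshold on the gray histogram, 3x3 morphological open then close,
    then the largest connected component.  Raises :class:`NoROIError` on a
    degenerate (constant or empty-foreground) image.
    """
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    if gray.min() == gray.max():
        raise NoROIError("degenerate histogram: constant image")
    thr = filters.threshold_otsu(gray)
    fg = gray > thr
    footprint = np.ones((3, 3), dtype=bool)
    fg = morphology.closing(morphology.opening(fg, footprint), footprint)
    if not fg.any():
        raise NoROIError("no foreground after thresholding")
    labels = measure.label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    mask = labels == keep
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    return mask, gray[y0:y1, x0:x1], (y0, x0, y1, x1)


def resize_square(img: AnnotatedImage, side: int = 608,
                  interp: str = "bilinear") -> AnnotatedImage:
    """Resize to side x side (the detector raster; side must divide by 32).

    Normalized box coordinates are scale-free, so annotations carry over
    unchanged under the direct (aspect-distorting) resize the pipeline uses.
    """
    if side <= 0 or side % 32:
        raise ConfigurationError(f"side must be a positive multiple of 32, got {side}")
    if img.pixels.shape[0] == side and img.pixels.shape[1] == side:
        return AnnotatedImage(img.pixels.copy(), list(img.objects),
                              img.degradation_tag, img.source_id)
    resample = Image.BILINEAR if interp == "bilinear" else Image.NEAREST
    out = np.asarray(Image.fromarray(img.pixels).resize((side, side), resample))
    return AnnotatedImage(out, list(img.objects), img.degradation_tag, img.source_id)


def line_occlusion(img: AnnotatedImage, cfg: OcclusionConfig,
                   rng: np.random.Generator | None = None) -> AnnotatedImage:
    """Paint regular stripes of width W every G+W pixels in the configured
    orientation(s); annotations are unchanged (small features survive between
    stripes).  W=0 leaves the image untouched."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    out = img.pixels.copy()
    color = np.asarray(cfg.color, dtype=np.uint8)
    h, wd = out.shape[:2]
    if cfg.orientation in ("horizontal", "both"):
        g = int(rng.integers(cfg.g_min, cfg.g_max + 1))
        w = int(rng.integers(cfg.w_min, cfg.w_max + 1))
        if w > 0:
            rows = np.arange(h) % (g + w) < w
            out[rows, :, :] = color
    if cfg.orientation in ("vertical", "both"):
        g = int(rng.integers(cfg.g_min, cfg.g_max + 1))
        w = int(rng.integers(cfg.w_min, cfg.w_max + 1))
        if w > 0:
            cols = np.arange(wd) % (g + w) < w
            out[:, cols, :] = color
    return AnnotatedImage(out, list(img.objects), img.degradation_tag, img.source_id)


def mosaic4(imgs: list[AnnotatedImage], side: int) -> AnnotatedImage:
    """Splice four images into a 2x2 grid at equal proportions.

    Each input is resized to side/2; each box is half-scaled and offset into
    its quadrant, so the output box count is the sum of the input counts.
    """
    if len(imgs) != 4:
        raise ConfigurationError(f"mosaic needs exactly 4 images, got {len(imgs)}")
    if side <= 0 or side % 2:
        raise ConfigurationError("mosaic side must be a positive even number")
    half = side // 2
    out = np.zeros((side, side, 3), dtype=np.uint8)
    objects = []
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]
    for img, (oy, ox) in zip(imgs, offsets):
        r = resize_square(img, half) if half % 32 == 0 else None
        if r is None:  # side/2 not detector-aligned; plain resize for tiles
            arr = np.asarray(Image.fromarray(img.pixels).resize((half, half),
                                                                Image.BILINEAR))
            r = AnnotatedImage(arr, list(img.objects), img.degradation_tag,
                               img.source_id)
        out[oy:oy + half, ox:ox + half] = r.pixels
        for cid, cx, cy, w, h in r.objects:
            objects.append((cid, (ox / side) + cx / 2, (oy / side) + cy / 2,
                            w / 2, h / 2))
    sid = "mosaic(" + ",".join(i.source_id for i in imgs) + ")"
    return AnnotatedImage(out, objects, "none", sid).validate()


def augment_training_image(img: AnnotatedImage, cfg: OcclusionConfig,
                           rng: np.random.Generator) -> AnnotatedImage:
    """Per-image training augmentation: stripe occlusion under the shared rng."""
    return line_occlusion(img, cfg, rng)
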