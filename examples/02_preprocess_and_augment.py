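"""Preprocessing and augmentation on a synthetic image.

Shows the conditioning chain — weighted-average grayscale, Otsu-threshold ROI
extraction, resize to the 608-px detector raster — and the two training
augmentations: white stripe occlusion and the 4-image mosaic splice.
"""

import numpy as np

from distilharvest import (CorpusSpec, OcclusionConfig, build_corpus,
                           extract_roi, line_occlusion, mosaic4, resize_square,
                           to_gray)

corpus, _plan = build_corpus(CorpusSpec(per_class_count=4, image_side=96,
                                        degrade_per_class=(0, 0), seed=1))
img = corpus[0]

gray = to_gray(img.pixels)
print(f"grayscale range: {gray.min()}..{gray.max()}")

mask, crop, (y0, x0, y1, x1) = extract_roi(gray)
print(f"ROI: rows {y0}..{y1}, cols {x0}..{x1} "
      f"({mask.sum()} foreground pixels) — the carrot body")

big = resize_square(img, 608)
print(f"resized raster: {big.pixels.shape[:2]}, box unchanged: "
      f"{big.objects == img.objects}")

occ = line_occlusion(img, OcclusionConfig(g_min=8, g_max=8, w_min=2, w_max=2,
                                          orientation="horizontal", seed=3))
changed = (occ.pixels != img.pixels).any(axis=2).mean()
print(f"stripe occlusion painted {changed:.0%} of pixels white; "
      f"annotations untouched")

mos = mosaic4(corpus[:4], 96)
areas = sum(b[3] * b[4] for b in mos.objects)
print(f"mosaic: {len(mos.objects)} boxes (one per quadrant), "
      f"total normalized box area {areas:.3f} (each input area quartered)")
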