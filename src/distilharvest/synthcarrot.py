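"""Synthetic carrot-defect corpus with the full degradation and split protocol.

No real corpus of harvester-conveyor defect imagery is publicly available, so this module renders a parametric
stand-in: carrot-like tapered blobs on a soil background, one per image, with
class-conditional geometry — a plain tapered root (``normal``), a forked root
(``bifurcate``), a dark longitudinal streak (``cracking``), a truncated root
(``breakage``) and a green-tinted crown (``greenroot``).  The generator then
applies the acquisition protocol: a 6:4 split by class into a clean teacher
partition ``T`` and a student partition ``S``, a 3:1:1 train/val/test split
within each, and a per-class quota of ``S`` images degraded by 2x or 4x
resolution reduction plus linear motion blur.

Everything is deterministic given ``CorpusSpec.seed``.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError

DEFECT_CLASSES = ("normal", "bifurcate", "cracking", "breakage", "greenroot")

DATASET_TEACHER = "T"
DATASET_STUDENT = "S"
SUBSETS = ("train", "val", "test")


@dataclass
class AnnotatedImage:
    """One image plus its YOLO-style annotations.

    ``objects`` holds ``(class_id, cx, cy, w, h)`` tuples with all coordinates
    normalized to [0, 1]; ``degradation_tag`` is one of ``none``/``x2``/``x4``.
    """

    pixels: np.ndarray
    objects: list[tuple[int, float, float, float, float]]
    degradation_tag: str = "none"
    source_id: str = ""

    def validate(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3")
        for cid, cx, cy, w, h in self.objects:
            if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
                raise ValueError(f"box out of range on {self.source_id}")
            if not 0 <= cid < len(DEFECT_CLASSES):
                raise ValueError(f"bad class id {cid}")
        return self


@dataclass
class CorpusSpec:
    """Declarative corpus description.  Defaults follow the acquisition protocol
    (3200 per class, 6:4, 3:1:1, 300 images at 2x + 276 at 4x per class) at a
    reduced raster; ``image_side=608`` reproduces the full-resolution raster."""

    per_class_count: int = 3200
    ts_ratio: tuple[int, int] = (6, 4)
    tvt_ratio: tuple[int, int, int] = (3, 1, 1)
    degrade_per_class: tuple[int, int] = (300, 276)
    image_side: int = 96
    blur_length: int = 7
    blur_angle: float = 0.0
    seed: int = 0

    def validate(self):
        if any(r <= 0 for r in self.ts_ratio) or any(r <= 0 for r in self.tvt_ratio):
            raise ConfigurationError("split ratios must be positive")
        if self.per_class_count <= 0:
            # zero-count corpus is empty, not an error; quotas are moot
            self.per_class_count = max(self.per_class_count, 0)
            return self
        if min(self.degrade_per_class) < 0:
            raise ConfigurationError("degradation quota must be >= 0")
        s_count = _allocate(self.per_class_count, self.ts_ratio)[1]
        if sum(self.degrade_per_class) > s_count:
            raise ConfigurationError(
                f"degradation quota {sum(self.degrade_per_class)} exceeds per-class "
                f"student-set size {s_count}")
        if self.image_side < 16:
            raise ConfigurationError("image_side too small")
        return self


@dataclass
class SplitPlan:
    """image_id -> (dataset in {T, S}, subset in {train, val, test})."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def members(self, dataset: str | None = None, subset: str | None = None):
        return [i for i, (d, s) in self.assignments.items()
                if (dataset is None or d == dataset) and (subset is None or s == subset)]


def _allocate(n: int, ratio) -> list[int]:
    """Split ``n`` items into len(ratio) groups; exact when divisible, else
    largest-remainder apportionment (ties to the earlier group)."""
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    counts = [int(q) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(ratio)), key=lambda i: (counts[i] - quotas[i], i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


@functools.lru_cache(maxsize=4)
def _grids(side: int):
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    return yy, xx


def _render(class_name: str, side: int, rng: np.random.Generator) -> AnnotatedImage:
    """Render one carrot of the given phenotype; always contains one object."""
    yy, xx = _grids(side)
    s = float(side)

    # soil-like background with grain
    img = np.empty((side, side, 3), dtype=np.float32)
    base = np.array([62, 48, 36], dtype=np.float32) + rng.uniform(-8, 8, 3)
    img[:] = base
    img += rng.uniform(-14, 14, (side, side, 1)).astype(np.float32)

    # carrot axis: mostly vertical, jittered
    theta = rng.uniform(-0.18, 0.18)
    cx = s * rng.uniform(0.42, 0.58)
    cy = s * rng.uniform(0.45, 0.55)
    length = s * rng.uniform(0.55, 0.72)
    radius = s * rng.uniform(0.10, 0.145)

    ct, st = np.cos(theta), np.sin(theta)
    u = (yy - cy) * ct + (xx - cx) * st          # along-axis, + toward tip
    v = -(yy - cy) * st + (xx - cx) * ct         # across-axis
    t = u / length + 0.5                         # 0 at crown, 1 at tip

    taper = rng.uniform(0.70, 0.82)
    r_t = np.maximum(radius * (1.0 - taper * t), 1.0)
    in_span = (t >= 0.0) & (t <= 1.0)

    if class_name == "bifurcate":
        t_fork = rng.uniform(0.40, 0.55)
        spread = radius * rng.uniform(1.0, 1.6)
        prong_r = np.maximum(0.55 * r_t, 1.0)
        off = spread * np.clip((t - t_fork) / (1.0 - t_fork), 0.0, None)
        forked = (np.abs(v - off) <= prong_r) | (np.abs(v + off) <= prong_r)
        mask = in_span & np.where(t <= t_fork, np.abs(v) <= r_t, forked)
    elif class_name == "breakage":
        t_cut = rng.uniform(0.45, 0.62)
        mask = (t >= 0.0) & (t <= t_cut) & (np.abs(v) <= r_t)
    else:
        mask = in_span & (np.abs(v) <= r_t)

    body = np.array([224, 116, 34], dtype=np.float32) * rng.uniform(0.88, 1.08)
    shade = 1.0 - 0.25 * np.clip(np.abs(v) / np.maximum(r_t, 1e-6), 0, 1) ** 2
    carrot = body[None, None, :] * shade[:, :, None]
    carrot += rng.uniform(-10, 10, (side, side, 1)).astype(np.float32)

    if class_name == "greenroot":
        t_green = rng.uniform(0.22, 0.35)
        green = np.array([76, 138, 52], dtype=np.float32)
        w_g = np.clip((t_green - t) / 0.08, 0.0, 1.0)[:, :, None]
        carrot = carrot * (1.0 - 0.85 * w_g) + green[None, None, :] * 0.85 * w_g

    img[mask] = carrot[mask]

    if class_name == "cracking":
        v0 = radius * rng.uniform(-0.35, 0.35)
        cw = max(1.0, 0.035 * s * rng.uniform(0.7, 1.3))
        t0, t1 = rng.uniform(0.08, 0.18), rng.uniform(0.78, 0.92)
        crack = mask & (np.abs(v - v0) <= cw) & (t >= t0) & (t <= t1)
        img[crack] = np.array([38, 20, 12], dtype=np.float32)

    ys, xs = np.nonzero(mask)
    x0, x1 = xs.min(), xs.max() + 1
    y0, y1 = ys.min(), ys.max() + 1
    cx_n = (x0 + x1) / 2.0 / s
    cy_n = (y0 + y1) / 2.0 / s
    w_n = (x1 - x0) / s
    h_n = (y1 - y0) / s
    cid = DEFECT_CLASSES.index(class_name)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels, [(cid, cx_n, cy_n, w_n, h_n)])


def motion_psf(length: int, angle_deg: float = 0.0) -> np.ndarray:
    """Normalized linear motion point-spread function.

    A line of the given pixel length at the given angle, splatted with
    bilinear weights onto a square kernel and normalized to sum to one
    (so it preserves mean intensity).  ``length<=1`` gives the identity.
    """
    length = int(length)
    if length <= 1:
        return np.ones((1, 1))
    a = np.deg2rad(angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    n = length if length % 2 == 1 else length + 1
    k = np.zeros((n, n))
    c = (n - 1) / 2.0
    for tt in np.linspace(-(length - 1) / 2.0, (length - 1) / 2.0, 8 * length):
        y, x = c + tt * sa, c + tt * ca
        iy, ix = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - iy, x - ix
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                if 0 <= iy + dy < n and 0 <= ix + dx < n:
                    k[iy + dy, ix + dx] += wy * wx
    return k / k.sum()


def degrade_image(img: AnnotatedImage, factor: int, blur_length: int = 7,
                  blur_angle: float = 0.0, interp: str = "bilinear") -> AnnotatedImage:
    """Resolution reduction by ``factor`` plus motion blur, restored to the
    original raster so annotation geometry is unchanged.

    The image is downsampled ``factor``-fold, convolved with a normalized
    linear-motion PSF, then upsampled back.  ``factor=1`` with
    ``blur_length<=1`` is the identity.
    """
    if factor not in (1, 2, 4):
        raise ConfigurationError(f"degradation factor must be 1, 2 or 4, got {factor}")
    h, w = img.pixels.shape[:2]
    if h % factor or w % factor:
        raise ConfigurationError(f"factor {factor} does not divide raster {h}x{w}")
    resample = Image.BILINEAR if interp == "bilinear" else Image.NEAREST
    arr = img.pixels
    if factor > 1:
        small = Image.fromarray(arr).resize((w // factor, h // factor), resample)
        arr = np.asarray(small)
    psf = motion_psf(blur_length, blur_angle)
    if psf.size > 1:
        out = np.empty_like(arr, dtype=np.float64)
        for c in range(3):
            out[:, :, c] = ndimage.convolve(arr[:, :, c].astype(np.float64),
                                            psf, mode="reflect")
        arr = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if factor > 1:
        arr = np.asarray(Image.fromarray(arr).resize((w, h), resample))
    tag = "none" if factor == 1 else f"x{factor}"
    return AnnotatedImage(arr, list(img.objects), tag, img.source_id)


def generate_corpus(spec: CorpusSpec) -> tuple[list[AnnotatedImage], SplitPlan]:
    """Render ``per_class_count`` images per class and build the split plan.

    Images are returned clean; apply :func:`apply_degradation_quota` for the
    degraded student subset.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    corpus: list[AnnotatedImage] = []
    plan = SplitPlan()
    for cname in DEFECT_CLASSES:
        ids = []
        for i in range(spec.per_class_count):
            im = _render(cname, spec.image_side, rng)
            im.source_id = f"{cname}_{i:05d}"
            corpus.append(im)
            ids.append(im.source_id)
        order = rng.permutation(len(ids))
        n_t, n_s = _allocate(len(ids), spec.ts_ratio)
        groups = {DATASET_TEACHER: [ids[j] for j in order[:n_t]],
                  DATASET_STUDENT: [ids[j] for j in order[n_t:]]}
        for dset, members in groups.items():
            counts = _allocate(len(members), spec.tvt_ratio)
            pos = 0
            for subset, cnt in zip(SUBSETS, counts):
                for sid in members[pos:pos + cnt]:
                    plan.assignments[sid] = (dset, subset)
                pos += cnt
    return corpus, plan


def apply_degradation_quota(corpus: list[AnnotatedImage], plan: SplitPlan,
                            spec: CorpusSpec) -> list[AnnotatedImage]:
    """Degrade exactly ``count_x2 + count_x4`` student-set images per class.

    Selection is uniform without replacement under ``spec.seed``, stratified
    over the S train/val/test subsets in proportion to their sizes so degraded
    images land in every subset whenever the quota allows (the protocol
    distributes them across all three sets).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    by_id = {im.source_id: i for i, im in enumerate(corpus)}
    n2, n4 = spec.degrade_per_class
    quota = n2 + n4
    for cname in DEFECT_CLASSES:
        members = {sub: sorted(i for i in plan.members(DATASET_STUDENT, sub)
                               if i.startswith(cname + "_")) for sub in SUBSETS}
        class_size = sum(len(v) for v in members.values())
        if quota > class_size:
            raise ConfigurationError(
                f"quota {quota} exceeds student-set size {class_size} for {cname}")
        if quota == 0:
            continue
        sizes = [len(members[s]) for s in SUBSETS]
        # one per non-empty subset first (the protocol spreads degraded images
        # over train/val/test), remainder proportional to subset size
        share = [1 if (sz > 0 and quota >= sum(1 for z in sizes if z > 0)) else 0
                 for sz in sizes]
        rest = _allocate(quota - sum(share), [max(sz - sh, 0) for sz, sh in
                                              zip(sizes, share)])
        share = [a + b for a, b in zip(share, rest)]
        chosen: list[str] = []
        for sub, cnt in zip(SUBSETS, share):
            pool = members[sub]
            if cnt > len(pool):
                raise ConfigurationError(f"quota exceeds {sub} subset for {cname}")
            pick = rng.choice(len(pool), size=cnt, replace=False)
            chosen.extend(pool[j] for j in pick)
        order = rng.permutation(len(chosen))
        for rank, j in enumerate(order):
            factor = 2 if rank < n2 else 4
            idx = by_id[chosen[j]]
            corpus[idx] = degrade_image(corpus[idx], factor, spec.blur_length,
                                        spec.blur_angle)
    return corpus


def build_corpus(spec: CorpusSpec) -> tuple[list[AnnotatedImage], SplitPlan]:
    """generate + degrade in one call."""
    corpus, plan = generate_corpus(spec)
    return apply_degradation_quota(corpus, plan, spec), plan


# ---------------------------------------------------------------------------
# disk interchange: PNG images, YOLO txt labels, TSV manifest

def write_corpus(corpus: list[AnnotatedImage], plan: SplitPlan,
                 outdir: str | Path, spec: CorpusSpec | None = None):
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in corpus:
        ipath = outdir / "images" / f"{im.source_id}.png"
        Image.fromarray(im.pixels).save(ipath)
        with open(outdir / "labels" / f"{im.source_id}.txt", "w") as fh:
            for cid, cx, cy, w, h in im.objects:
                fh.write(f"{cid} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")
        dset, subset = plan.assignments[im.source_id]
        cls = im.source_id.rsplit("_", 1)[0]
        rows.append((im.source_id, str(ipath), cls, dset, subset, im.degradation_tag))
    with open(outdir / "manifest.tsv", "w", newline="") as fh:
        wtr = csv.writer(fh, delimiter="\t")
        wtr.writerow(["image_id", "path", "class", "dataset", "subset", "degradation_tag"])
        wtr.writerows(rows)
    if spec is not None:
        import yaml
        with open(outdir / "corpus_spec.yaml", "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in vars(spec).items()}, fh,
                           sort_keys=False)
    return outdir / "manifest.tsv"


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_image(row: dict) -> AnnotatedImage:
    pixels = np.asarray(Image.open(row["path"]).convert("RGB"))
    lbl = Path(row["path"]).parent.parent / "labels" / f"{row['image_id']}.txt"
    objects = []
    if lbl.exists():
        for line in lbl.read_text().splitlines():
            p = line.split()
            objects.append((int(p[0]), *(float(x) for x in p[1:5])))
    return AnnotatedImage(pixels, objects, row["degradation_tag"], row["image_id"])
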