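# distilharvest

Surface-defect detection for crops photographed during combine harvesting,
where machine vibration and fast conveyor motion blur the images. The package
implements a **multi-stage knowledge-distillation detector**: a
full-resolution yolo-v5-style *teacher* trained on clean imagery guides a
lightweight, channel-pruned mobilenetv2-backbone *student* trained on
resolution-degraded imagery, so the student learns to recognize defect
features that blurring has partially destroyed.

It is aimed at researchers in agricultural machine vision who want a fully
inspectable, CPU-only reference implementation of the complete pipeline:
corpus construction and degradation, preprocessing and augmentation, the two
detector architectures, batch-norm channel pruning, the multi-stage
distillation objective, and mAP evaluation. The neural-network layer is a
small NumPy reverse-mode autograd engine contained in the package, so every
gradient is reproducible bit-for-bit from a seed.

## The method

**Task.** Five carrot phenotype classes — *normal, bifurcate, cracking,
breakage, greenroot* — localized with one bounding box per root. The corpus
protocol splits images 6:4 by class into a clean partition **T** (teacher)
and a partition **S** (student), splits each 3:1:1 into train/val/test, and
degrades a fixed per-class quota of S by 2× or 4× resolution reduction plus
convolution with a normalized linear motion point-spread function.

**Student construction.** The student keeps the teacher's FPN+PAN neck and
three detection heads but swaps the backbone for inverted-residual blocks
(1×1 expand → 3×3 depthwise → 1×1 linear projection, relu6). Training adds
an L1 penalty λ·Σ|γ| on the batch-norm scales; afterwards the 80 % quantile
of the pooled |γ| sets a **global threshold** and every channel below it is
removed, with add-junction partners aligned by mask union and each removed
channel's β folded into its consumers:

    z = (z_in − μ) / √(σ² + ε),   z_out = γ·z + β        (BN; γ→0 ⇒ channel is dead)

**Distillation.** Four teacher stages (backbone pyramid, FPN outputs, PAN
outputs, prediction layer) supervise the student. Where a stage taps several
teacher maps they are cascaded and fused SK-style — a pooled descriptor
Z = FC(GAP(cascade)) drives matrices A, B whose softmax pair

    a = e^{AZ} / (e^{AZ} + e^{BZ}),   b = e^{BZ} / (e^{AZ} + e^{BZ}),   a + b = 1

mixes the branches channelwise. Each stage loss is a four-scale pooled L2
regression, TtL_i = Σ_k L2(ap_k(FM_t), ap_k(FM_s)), and the total objective is

    L_total = α·TtL1 + β·TtL2 + θ·TtL3 + γ·TtL4 + L_obj,
    α = 0.1, β = 0.2, θ = 0.5, γ = 0.2

with L_obj the ordinary single-stage detection loss (BCE objectness + BCE
class + CIoU box). During distillation the frozen teacher sees the *clean*
rendering of each scene while the student sees the *degraded* one.

No public corpus exists for this task, so `synthcarrot` renders a synthetic
stand-in (class-conditional carrot silhouettes on a soil background) and
applies the full protocol; everything downstream is exercised end-to-end on
it.

## Worked example

`python examples/01_generate_corpus.py` builds a 50-image corpus and prints
the protocol arithmetic:

```
total images: 50
teacher set T: 30, student set S: 20
degradation tags: {'none': 30, 'x2': 10, 'x4': 10}
  ('S', 'test'): 5 images
  ('S', 'train'): 10 images
  ('S', 'val'): 5 images
  ('T', 'test'): 5 images
  ('T', 'train'): 20 images
  ('T', 'val'): 5 images
first image normal_00000: class 0, box centred at (0.53, 0.52), 0.23 x 0.62 (normalized)
```

50 images split exactly 6:4 into T/S and 3:1:1 within each; 2+2 student
images per class carry the x2/x4 degradation tags. The other examples walk
through preprocessing/augmentation (`02`), pruning (`03`, parameters
122 906 → ~11 000 at the 80 % threshold) and a miniature distillation run
(`04`, prints the per-stage TtL breakdown and the distilled vs unsupervised
test mAP@0.5).

The `distilharvest` CLI wraps the same library calls
(`generate | prep | train-teacher | sparsity-train | prune | distill | eval`);
exit codes are 0 / 1 / 2 for success / configuration error / data error.

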