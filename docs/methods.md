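# Methods

This note records the models, the synthetic-data design, the numerical
choices and the knobs that matter, in the package's own terms.

## The model pair

**Teacher** (`detnet.TeacherNet`): a yolo-v5-family single-stage detector.
Focus stem (stride-2 space-to-depth shuffle + 3×3 conv), four stride-2
CSP-bottleneck stages, SPP (5/9/13 max-pools) at the deepest level, an FPN
top-down neck followed by a PAN bottom-up pass, and three 1×1 prediction
heads at strides 8/16/32. Activations are leaky-relu (slope 0.1);
`width_multiple`/`depth_multiple` scale channel counts and bottleneck
repeats. Backbone taps halve the spatial side stage by stage, so a 608-px
input yields 304/152/76/38/19 and head grids 76/38/19.

**Student** (`detnet.StudentNet`): the same neck/head geometry fed by a
mobilenetv2-style backbone — a stride-2 stem and five inverted-residual
stages (1×1 expand ×6 → 3×3 depthwise → 1×1 linear project, relu6,
residual add at stride 1 with matching channels). The last three
downsampling outputs replace the teacher's p3/p4/p5. Dropout (default 0.6, the
full-scale operating point; desk runs use 0.1 because the desk-scale
student is far below the overfitting regime that motivates heavy dropout) is applied to the backbone output during training.

**Detection loss.** BCE objectness and class terms plus CIoU box
regression, with yolo-style assignment: every anchor within a 4× wh-ratio
of the box, at the centre cell and its two nearest neighbours; a box
matching no anchor falls back to its best wh-IoU anchor. The objectness
BCE is averaged separately over positive and negative cells and summed —
at desk scale positives are a few cells in thousands, and a plain mean
silently ignores them. Per-level balance 4.0/1.0/0.4, term gains
box 0.05 / obj 1.0 / cls 0.5. Anchors are 3-per-level k-means centroids of
the corpus box sizes.

## Channel pruning

Sparsity training adds the L1 subgradient λ·sign(γ) (default λ = 1e-4) to
the gradients of every *prunable* BN scale. The removal threshold is one
global quantile (default 0.8 = the stated removal share) of pooled |γ|;
quantiles are taken on |γ| because the affine sign is absorbed by the
following convolution. Mask rules:

- prediction heads and the stem are never pruned; depthwise BNs are
  *followers* whose mask copies their input mask;
- layers meeting at a tensor addition (bottleneck chains, inverted-residual
  chains) are aligned to the **union** of their keep-masks — lossless with
  respect to surviving channels, at the cost of keeping slightly more than
  the target fraction;
- every layer keeps at least its largest-|γ| channel (floor rule).

Reconstruction slices convolutions on output channels by their own mask and
input channels by the upstream mask. A removed channel's eval-mode output
is approximated by its γ→0 limit, the constant act(β); that constant is
folded into each consumer (bias for plain convs, running-mean shift for
conv+BN units; computed exactly through depthwise units). The fold is exact
everywhere when the removed (γ, β) are zero — the equivalence oracle in the
tests — and exact away from zero-padded borders otherwise, because a
constant input stops being constant inside the padding fringe. Fine-tuning
after pruning (step 3) absorbs any residual border effect.

## Distillation

Stage pairing (configurable; defaults):

| stage | teacher taps | student tap |
|---|---|---|
| TtL1 | backbone p3, p4, p5 (cascade-fused) | backbone p5 |
| TtL2 | FPN output n1 | neck n1 |
| TtL3 | PAN outputs n2, n3 (fused) | neck n3 |
| TtL4 | prediction layer (19-grid head) | head output |

Multi-map stages fuse pairwise with the SK-style softmax pair; A and B are
per-stage trainable matrices (descriptor dimension C/2, minimum 4).
Teacher branches of differing width are aligned by trainable 1×1
projections and adaptive average pooling to the deepest tap's raster; the
student side gets its own 1×1 projection when channel counts differ. All
fusion/adapter parameters train jointly with the student; the teacher is
frozen, and since its tap set over a fixed clean training set is constant,
the taps are computed once per run and cached.

Each TtL is the sum over pooling output sizes (1, 2, 4, 8) of the mean
squared difference of the average-pooled maps; sizes larger than the map
side clamp to the side. The total objective applies the stage weights
α = 0.1, β = 0.2, θ = 0.5, γ = 0.2 and adds the unmodified detection loss;
the logged breakdown satisfies the decomposition identity exactly at every
step. L_obj uses ground truth only — the teacher influences the student
solely through features.

## Synthetic corpus

Each image is one carrot-like root on a noisy soil background: a tapered
tube around a jittered near-vertical axis, with class-conditional edits —
a forked tip (*bifurcate*), a dark longitudinal streak (*cracking*), a
truncated root (*breakage*), a green-blended crown (*greenroot*). The box
is the mask's bounding rectangle. Geometry, color and noise draw from one
`numpy` generator seeded by the corpus spec, so corpus, splits and
degradation assignments are byte-reproducible.

Degradation downsamples by 2× or 4× (bilinear), convolves with a
normalized linear-motion PSF (default length 7 px, angle 0°, both
configurable; the protocol fixes no kernel, so these are declared
defaults), and upsamples back to the original raster so one annotation
geometry serves all images. Normalizing the PSF to unit sum preserves mean
intensity to within rounding. Degraded images are drawn without
replacement, spread over S-train/val/test (one guaranteed per non-empty
subset when the quota allows, remainder proportional to subset size).

What the generator does *not* emulate: real lighting, occlusion by
neighbouring roots, soil adhesion, camera noise statistics, multiple
objects per frame, or the class imbalance of a field census. Passing tests
therefore demonstrate that the machinery — protocol arithmetic, shapes,
losses, pruning algebra, training dynamics — is correct, not that the
reported field accuracies transfer.

## Desk-scale study conditions

All training-dependent checks run one profile, fixed in
`acceptance_protocol.py`: 96-px rasters; 30 images per class; degradation
quota 3+2 per class (≈ the protocol's 45 % degraded share of S); teacher width
0.25, student width 0.5 (the student must survive 80 % channel removal with
usable capacity); Adam, lr 3e-3 with cosine decay to 10 %, batch 8;
60 epochs teacher, 25 epochs sparsity training, 50 epochs for each arm of
the paired distilled/unsupervised comparison, which is reported as the
median over three paired seeds. Every training phase selects its final
parameters on the matching validation split (val mAP@0.5, checked every
five epochs), as the two-verification-set protocol intends; besides being
faithful, this damps the epoch-to-epoch oscillation that dominates
small-sample training. The full-scale hyperparameters (lr 1e-4, batch 64,
300 epochs, 608-px input) remain the config defaults; the desk profile
raises the learning rate because 50-epoch schedules at 1e-4 leave every
model far from convergence, which would make the comparison meaningless.

## Evaluation

Greedy score-descending matching with a one-match-per-truth rule defines
TP/FP at an IoU threshold. AP offers two areas under the PR curve:
`trapezoid` (exact trapezoidal area over the full score sweep — the form
checked against a brute-force threshold enumeration to 1e-6) and
`interp101` (COCO-style 101-point interpolation, the default for detector
mAP). mAP is the arithmetic mean of per-class APs; mAP@[0.5:0.95] averages
over the ten COCO IoU thresholds. Confusion matrices are image-level: the
prediction is the class of the highest-scoring detection, with a "missed"
column for images with no surviving detection; ratio metrics with zero
denominators are reported as undefined rather than zero.

## Known limitations

- The autograd engine is single-threaded NumPy; full-scale training
  (608 px, batch 64, 300 epochs) is out of reach, by design.
- β-folding is approximate at zero-padded borders when removed channels
  have γ ≠ 0 (see above).
- The desk-scale distillation benefit is a directional, stochastic result
  with small margins; it establishes the ordering of the
  supervised-vs-unsupervised comparison, not effect magnitudes that
  would transfer to field imagery.
- `line_occlusion` draws one (G, W) pair per orientation per call; drawing
  per segment is a plausible alternative reading of the protocol.
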