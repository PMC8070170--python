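# Methods

## Problem and model

`nodulefusion` classifies the subpathological type of malignant lung nodules
seen in low-dose spiral CT (LDCT) screening: *preinvasive lesions* (PILs —
minimally invasive adenocarcinoma, adenocarcinoma in situ, and atypical
adenomatous hyperplasia, grouped because their post-surgical survival is
near-identical) versus *other* nodules (invasive adenocarcinoma and benign
lesions). PIL is the positive class. The input for one case is an ordered
stack of grayscale slices at assumed 1 mm spacing, a doctor-drawn bounding
rectangle around the nodule, the index of the reference center slice, and
the biopsy label.

The model is a two-branch hybrid:

**2D branch.** From the center slice, a 32×32 patch is cropped at the
midpoint of the annotation rectangle and expanded into three channels: the
raw crop, a Local Binary Pattern (LBP) texture map, and a binary Canny edge
map. LBP and edge maps inject texture and boundary cues that are otherwise
hard to recover from a low-resolution, low-dose patch.

**3D branch.** A 32×32×7 sub-volume (three slices either side of the center
slice) captures the depth extent of the nodule.

Both branches share one architecture: a stem convolution (3×3, batch norm,
ReLU), max pooling, then three *average-max attention residual blocks* in
series, global average pooling to a 256-dim feature vector, and a single
sigmoid logit. A block computes a conv-transformed feature map
`X_F = BN(Conv(BN(Conv(x)) → ReLU))`, derives a per-channel weight

    w = ReLU(f_m(max(X_F))) + ReLU(f_a(avg(X_F)))

from the global per-channel maximum and mean (`f_m`, `f_a` are learned 1×1
convolutions over the channel vector), and outputs
`direct(x) + w ⊙ X_F`, where the direct connection is a strided 1×1
convolution plus batch norm that matches shapes. The weights are
non-negative by construction (ReLU outputs) and act as channel attention:
channels whose global statistics look informative are amplified. There is
no activation after the residual addition.

**Fusion.** After both branches are trained (independently, on the same
labels), each case is summarized by the two pooled 256-vectors,
concatenated 3D half first into a 512-dim fused vector. An XGBoost
classifier over fused vectors produces the final score; trees can exploit
non-linear interactions between planar-texture features and depth-extent
features that neither linear head sees.

**Loss and optimization.** Binary cross-entropy over sigmoid outputs — soft
labels are allowed, because CutMix produces them — plus an L2 penalty
`α Σ‖w‖²` over convolution and linear weights (biases and batch-norm
parameters are not penalized; the printed form of the training objective
omits the leading minus sign, and the standard negative log-likelihood is
implemented so the loss is non-negative and minimized at a perfect fit).
Optimization is SGD with momentum; the learning rate decays geometrically,
`lr(e) = lr₀ · 0.9^⌊e/10⌋`, so an initial 0.02 becomes 0.018 at epoch 10.
Parameters are He-initialized (zero-mean normal, variance `2/fan_in`),
batch-norm scale 1 and shift 0.

## Implementation of the networks

The branch networks run on a compact numpy layer library with explicit
forward/backward passes (`nodulefusion.nn`). Convolutions are evaluated as
im2col + BLAS matrix products, and input gradients as stride-dilated
transposed convolutions through the same path, so every heavy operation is
a matmul. Every layer's analytic gradient is verified against central
differences in the test suite (conv 2D/3D with stride, batch norm in
training mode, max pooling, and the full attention block including the
max/mean pooling paths). All computation is float64 and deterministic given
the seed.

## Tunable parameters

| Parameter | Default | Origin |
| --- | --- | --- |
| initial learning rate (2D / 3D) | 0.004 / 0.02 | published setting |
| LR decay | ×0.9 every 10 epochs | published setting |
| L2 coefficient α | 1e-6 | published setting |
| online CutMix probability | 0.5 | published setting |
| offline expansion factors (pos / neg) | 80 / 48 | implied by the published counts 576→46,080 and 976→46,848 |
| GBT: max depth / learning rate / rounds | 8 / 0.02 / 60 | published setting |
| momentum | 0.9 | our choice (not stated) |
| batch size | 16 (pipeline), 32 (library default) | our choice |
| epochs (miniature pipeline, 2D / 3D) | 12 / 8 | our choice, see scale below |
| block channels | (64, 128, 256); (16, 32, 256) in the miniature pipeline | last block fixed at 256 by the fusion contract; the progression is otherwise free |
| LBP | 8 neighbours, radius 1, ≥ tie convention, code/255 | our choice of the classic square-neighbourhood operator |
| Canny | σ = 1.0, hysteresis at gradient-magnitude quantiles 0.10/0.30 | our choice, biased low to keep as many edges as possible |
| crop convention | patch rows `[i_c−16, i_c+16)`, center at index 16; out-of-bounds zero-padded | our choice |

## Synthetic phantom generator

No patient data ships with the package; `nodulefusion.synthetic` generates
phantom cases whose class structure mirrors the radiological cues reported
for the two classes: positives are small ellipsoidal blobs with uniform
interior density and near-circular boundaries; negatives are larger, with
smooth multiplicative speckle inside (uneven intensity), sinusoidally
lobulated boundaries, and, with probability 0.3, an adjacent bright
vessel-like tube. Defaults: 64×64×16 volumes, positive in-plane radii
3–6 px, negative 7–11 px, speckle amplitude 0.35, lobulation 0.30,
background noise SD 0.02, Gaussian boundary smoothing σ = 1. Homogeneous
noiseless positives keep an exactly uniform interior so the "uniform
density" property is testable. The default dataset is a 1/8-scale miniature
of the published composition: 72 positive + 122 negative training cases,
25 + 25 test.

The phantom deliberately omits much of real LDCT: no Hounsfield
calibration or windowing, no lung anatomy or pleural attachment, no scanner
noise texture or reconstruction artifacts, no inter-reader variability in
the rectangles, and a class contrast (size/texture/boundary) that is far
cleaner than real PIL-vs-IA overlap. Passing the end-to-end tests therefore
shows that the implementation learns and fuses the intended cues, not that
the model would reach any particular accuracy on hospital data.

## Problem sizes and study scale

The miniature study trains the 2D branch 12 epochs and the 3D branch 8
epochs with channel widths (16, 32, 256) and batch 16 on the 194-case
phantom training set. At this scale both branches typically reach test AUC
approaching 1.0 on the phantom task, and training the full pipeline takes
minutes on a single CPU core. The 256-dim feature contract, and with it the
512-dim fused vector, is unchanged from the full-scale design.

## Numerical choices

- Predictions are clamped to `[1e-7, 1 − 1e-7]` inside the loss so `ln 0`
  never occurs; training aborts with a diagnostic on non-finite loss.
- Batch norm uses eps 1e-5 and running-statistics momentum 0.1; inference
  always uses running statistics.
- Per-case intensities are min-max scaled to [0, 1]; a constant stack maps
  to zeros rather than dividing by zero.
- LBP ties (neighbour equal to center) count as "≥", so a constant patch
  carries the all-ones code; border pixels replicate edge values.
- Max pooling pads odd extents with −inf; gradient flows to the first
  argmax on exact ties.
- ROC ties are grouped at one threshold; AUC is trapezoidal and equals the
  Mann–Whitney U identity (property-tested).
- Metrics with zero denominators (e.g. sensitivity with no positives) are
  reported as NaN with a warning rather than silently coerced.

## Design choices where the design was open

- **Channel attention is global**: the per-channel weight uses global max
  and mean pooling (one scalar per channel), the standard channel-attention
  reading; no channel-reduction bottleneck in `f_m`/`f_a`.
- **Downsampling** by stride 2 in the first conv of blocks 2 and 3, carried
  by the 1×1 direct connection; the 3D stem pools all three axes so the
  seven-slice depth axis is reduced early.
- **Single-logit sigmoid head** rather than a two-way softmax, matching the
  binary cross-entropy loss.
- **CutMix** follows the original sampler (area ratio from a uniform draw,
  uniform center, clipped box), applied batch-wise with within-batch
  partners; a 3D sample is cut through its full depth extent, so the label
  mixes by in-plane area in both branches.
- **GBT stage** uses xgboost with the published depth/rate/rounds, binary
  logistic objective, all unstated knobs at library defaults; it is trained
  on the un-augmented per-case fused vectors (one vector pair per case),
  and scores map to probabilities through the logistic link.
- **Sample archives** are compressed array bundles (`.npz`); annotations
  and feature tables are CSV.

## Known limitations

- The paper-scale experiment (1552 training cases from hospital LDCT, the
  published accuracy/sensitivity/specificity table) cannot be reproduced
  here; the phantom study checks pipeline behaviour, not clinical
  performance.
- On the phantom task both branches usually saturate near-perfect test
  accuracy, which leaves the boosted-tree fusion stage little headroom: it
  ties with, and on some seeds trails by one test case, the best single
  branch. The regime where fusion demonstrably adds accuracy — imperfect,
  complementary branches — is exercised separately by a dedicated
  complementary-signal (XOR-style) fusion test.
- Offline expansion at the published factors (80/48) is validated for
  counts and label preservation, but the miniature pipeline trains without
  offline expansion (online CutMix only) to keep single-CPU runtimes low.
- LBP and Canny parameters are fixed heuristics, not tuned against any
  clinical reference.
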