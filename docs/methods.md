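# Methods

## Problem and pipeline

`pathgait` recognizes pathological gait patterns (festinating, scissor,
hemiparetic, shuffling, normal) from side-view binary silhouette sequences.
The pipeline is: silhouette preprocessing → automatic gait-cycle
segmentation → per-cycle energy templates (GEI, GEnI, AEI) → weighted fusion
into a single FEI per cycle → a lightweight dual-branch convolutional
classifier. One gait cycle yields one classification sample.

## Preprocessing

Raw grayscale masks are thresholded (default 127), cleaned by morphological
opening then closing with a square (2r+1)×(2r+1) element (default r = 1;
the open-then-close composition is an alternating filter and therefore
idempotent), cropped to the largest 8-connected component, scaled
isotropically with nearest-neighbor interpolation so the silhouette height
is exactly 256, and horizontally centered on the foreground centroid in a
256×256 frame. Nearest-neighbor interpolation keeps masks strictly binary.
Largest-component cropping stands where a person detector would run in a
camera pipeline; on clean silhouettes the two agree, and a detector can be
substituted behind the same interface.

## Gait-cycle segmentation

The silhouette contour is taken as the Sobel gradient magnitude thresholded
at > 0 and restricted to foreground (the one-pixel inner boundary ring).
Per frame, the width/height ratio of the contour's axis-aligned tight
bounding rectangle is recorded; the "smallest outer rectangle" is
implemented axis-aligned, matching the width/height language of the
procedure. The series is smoothed by a centered moving average (default
window 5, odd) with edge-value padding — reflection padding would convert a
monotone approach to either boundary into a spurious boundary maximum and
hide boundary troughs.

Troughs (legs-together poses) are local minima with a prominence of at
least 0.02 and pairwise separation of at least 3 frames (defaults; the
source procedure states neither). Boundary frames additionally count as
troughs when the series rises strictly away from them by at least the
prominence before the nearest interior trough: a walking pass routinely
begins or ends at (or just short of) a legs-together pose, and without
boundary troughs the first and last half-cycles are unrecoverable. Two
adjacent troughs are half a cycle; a full cycle spans three consecutive
troughs, with the shared boundary frame belonging to both neighboring
cycles. Partial leading/trailing half-cycles are discarded.

## Energy templates

For a cycle of N binary frames F_t ∈ {0, 255}:

- **GEI**(x,y) = (1/N) Σ_t F_t(x,y). Foreground is encoded 255 so the mean
  lands directly in [0, 255].
- **GEnI**: per pixel, p₁ = foreground frequency, H = −Σ p_j log₂ p_j
  (binary, K = 2, 0·log 0 := 0), then min–max scaled to [0, 255]. A
  degenerate field (H_max = H_min, e.g. a fully static cycle) yields an
  all-zero image with a warning.
- **AEI**(x,y) = (1/(N−1)) Σ_{t=2..N} |F_t − F_{t−1}|. The printed form of
  this template elsewhere sums t = 1..N against an undefined F₀ with a 1/N
  factor; the (N−1) pairwise convention used here is internally consistent
  and lets a fully alternating pixel reach 255.

All three are symmetric under frame-order reversal and are verified in the
tests against independent per-pixel loop implementations.

## Template fusion by batch gradient descent

The three templates (pixels rescaled to [0, 1]) form the columns of
X ∈ R^{65536×3}; a target image y is approximated by Xw minimizing
cost(w) = ‖y − Xw‖². Full-batch gradient descent starts from the uniform
w = 1/3 (and, on restarts, from seeded Dirichlet(1,1,1) simplex draws);
each step is followed by the exact Euclidean projection onto the
probability simplex (negative components end at zero, the vector sums to
one), so the final weights always describe a convex combination. The naive
clip-then-divide-by-sum rescaling was rejected: radial rescaling is not an
orthogonal projection and admits spurious fixed points (gradient parallel
to w rather than constant across the support), to which the descent
demonstrably converges on ill-conditioned template sets; the Euclidean
projection makes the iteration a textbook projected gradient method whose
fixed points are exactly the constrained minima. Descent stops when |Δcost| < 10⁻⁸ or after 5000 iterations;
of 5 restarts the smallest final cost wins. Weights are fitted per cycle —
different cycles have different optimal weights.

Numerical notes. Because the cost is quadratic in only three weights, the
gradient −2Xᵀ(y − Xw) is evaluated from the precomputed 3×3 Gram matrix
XᵀX and vector Xᵀy — algebraically identical to the full-batch computation
and O(1) per iteration. The gradient is divided by n_pixels (an MSE-scale
step), making step sizes image-size independent; when no learning rate is
given, 1/trace(2XᵀX/n) is used, which is stable because the trace bounds
the largest curvature eigenvalue. Planted convex combinations are recovered
to < 10⁻³ and match an SLSQP constrained-least-squares oracle in the tests.

The fusion **target is not canonical** — the procedure this implements never
defines it. It is therefore a caller-supplied parameter; the pipeline
default is the per-pixel maximum of {GEI, GEnI, AEI}, which makes the FEI
emphasize every template's high-energy regions while remaining a convex
combination of them.

## Classifier

A width-1.0 MobileNetV2-style feature stack (inverted residuals, linear
bottlenecks, ReLU6, stride 32, final 1×1 expansion to 1280 channels) is
shared by two branches: the convolutional branch passes the feature map
through unchanged; the attention branch applies the parallel attention
block

    F2 = M_c(F) ⊗ M_s(F) ⊗ F,

with channel attention M_c = σ(MLP(avgpool F) + MLP(maxpool F)) (one shared
bottleneck MLP, reduction 16) and spatial attention
M_s = σ(pointwise₁ₓ₁(depthwise₇ₓ₇([F̄_avg ; F̄_max]))) over the 2-channel
per-pixel channel-mean/max stack. Both maps are computed from the original
F, so their evaluation order is irrelevant — the property that separates
this block from the serial channel-then-spatial variant, and the property
the tests assert. Branches are fused by elementwise sum, and a customized
head classifies: depthwise 3×3 → pointwise to 32 channels (a
depthwise-separable convolution in place of global average pooling, so
spatial positions get learned weights) → flatten → dense(256) → batch norm
→ ReLU → dropout(0.2) → dense(5) → softmax.

Where the architecture description is silent, the parameter budget decides:
a **shared** backbone and **sum** fusion (two backbones or concatenation
would overshoot the ~3.01 M budget), head widths 32/256, reduction 16, MLP
hidden rectifier with biases everywhere. With these choices the trainable
counts are architecture-determined: 3,009,692 (3.01 M) at 256×256 input,
2,886,812 (2.89 M) at 224×224 (only the flatten→dense matrix changes:
32·(8²−7²)·256 = 122,880), backbone 2,223,296, attention block 206,263 —
which is 206,258 ≈ 0.21 M more than the 5-parameter 1-D-conv
channel-attention (ECA-style) variant. The squeeze-excitation and serial
CBAM variants land at 3.01 M as well. Input is the single-channel FEI
scaled to [0, 1]; a 1-channel stem is used unless weights pretrained on RGB
images are loaded (then the gray image is replicated to 3 channels).

The network is implemented directly on numpy: every layer carries an
explicit forward and backward pass (1×1 convolutions as channel matmuls,
depthwise convolutions as kernel-tap loops over strided slices, the stem
via im2col; batch norm with train/eval statistics; inverted-residual
shortcuts). All backward passes are verified against central finite
differences in the test suite. A `no_grad` context disables backward caches
for inference-scale memory use.

## Training and evaluation

Adam (β = 0.9/0.999), cross-entropy loss, minibatch 32, stratified seeded
80/20 train/test split at the cycle level. The reference recipe's defaults
are learning rate 10⁻⁴ and 100 epochs. Transfer learning = loading backbone
weights from a file and freezing them; the attention block and head retrain
from fresh initialization. With a frozen backbone, feature maps are
computed once per sample and cached — gradients are identical, epochs are
orders of magnitude faster.

Backbone batch norm during feature extraction uses batch statistics over a
fixed batch partition (deterministic given the data order): an untrained or
freshly loaded backbone has no meaningful running statistics, and batch
statistics are the only normalization that keeps activations scaled through
50+ layers of a randomly initialized network.

Metrics from the confusion matrix (percentages): accuracy = Σᵢ TPᵢ / N;
per-class precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F1 = 2PR/(P+R); macro values are unweighted class means, and a
class with a zero denominator contributes 0 with a warning. Cycle-level
splitting permits same-subject leakage across splits; that is the protocol
replicated here, and the synthetic generator has no subject identity to
leak.

## Synthetic walker generator

Real pathological-gait video is clinical data; the generator provides a
fully specified substitute with known ground truth. Each frame renders a
side-view walker from closed-form geometry (head disc, trunk-lean-rotated
torso ellipse, two legs as hip→knee→foot capsules) on a 256×256 binary
canvas. Horizontal foot offsets follow ±(stride/2)·sin(2πt/cycle_frames),
so the aspect-ratio series has exact minima every cycle_frames/2 frames;
those indices (including both boundary frames — the pass starts at a
legs-together pose and ends one frame short of one) are emitted as ground
truth. `cycle_frames` must be even so troughs land on integer frames.
Optional salt noise flips each pixel with probability `noise_rate`
(≤ 0.05); noisy sequences are routed through preprocessing, whose opening
removes the speckle, before cycle detection.

Class styles are deliberate caricatures of the clinical descriptions,
chosen once for template separability rather than biomechanical realism:
normal (cycle 20 frames, stride 70 px, lift 12 px), festinating (16, 52,
lean 14°), scissor (22, 50, knees crossing 0.7), hemiparetic (22, 60, one
leg's swing halved), shuffling (26, 26, lift 2 px, lean 6°). Dataset
generation jitters stride (±10%), cadence (±2 frames), lean, lift,
asymmetry and crossing per sample from a seeded generator, with exactly
balanced classes. Identical parameters and seed give bit-identical frames.

What the generator does **not** emulate: segmentation artifacts beyond
i.i.d. salt noise (holes, shadows, merged blobs), camera perspective and
scale change along the walkway, clothing/carrying variation, arm swing,
inter-subject anatomy, or any subject identity. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the method
separates geometrically distinct gait styles; they do not certify accuracy
on clinical video.

## Benchmark problem sizes

The packaged five-class benchmark uses 40 cycles per class (≈ 15 three-cycle
passes per class at 1% noise), a frozen randomly initialized backbone, and
15 epochs of Adam at learning rate 10⁻³ — the standard Adam default, chosen
as the study condition for this short schedule (the 10⁻⁴/100-epoch recipe
remains the `TrainConfig` default). Under these conditions the classifier
reaches ≥ 90% test accuracy on the 8-per-class held-out cycles in a few
minutes on one CPU. The acceptance script reports only the two
architecture-determined parameter counts, which involve no data at all.

## Known limitations

- The numpy network trains the attention block and head well, but full
  backbone fine-tuning, while implemented and gradient-checked, is slow at
  256×256 on one CPU (minutes per epoch); the frozen-backbone regime is the
  intended use without an accelerator.
- No pretrained backbone weights ship with the package; transfer learning
  requires a caller-supplied `.npz` (e.g. exported from a trained run of
  this package). `pretrained=True` without a file raises immediately.
- Trough detection assumes the aspect-ratio signal outlives smoothing;
  pathologically small strides with wide clothing-like silhouettes could
  flatten it below the 0.02 prominence default, which is then the knob to
  lower.
- The fusion target choice is a documented guess (see above); per-target
  FEIs differ, and downstream accuracy comparisons should state the target.
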