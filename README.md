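# pathgait

Side-view pathological gait recognition from binary silhouette sequences.

Gait abnormalities — the festinating and shuffling gaits of Parkinson's
disease, the scissor gait of spastic paraplegia, the circumducting gait of
hemiparesis — are visible in how a person's silhouette evolves over one
walking cycle. `pathgait` implements a full recognition chain for
clinicians' screening tools and gait-analysis researchers:

1. **Preprocessing** — threshold, morphologically clean, crop to the
   largest connected component, and normalize silhouettes to 256×256 with
   the body height filling the frame.
2. **Gait-cycle segmentation** — the width-to-height ratio of the
   silhouette contour's bounding rectangle oscillates with the leg swing;
   its troughs mark legs-together poses, two adjacent troughs are half a
   cycle, and a full cycle spans three consecutive troughs.
3. **Energy templates** per cycle of `N` binary frames `F_t ∈ {0, 255}`:
   - gait energy image `GEI(x,y) = (1/N) Σ_t F_t(x,y)`
   - gait entropy image `GEnI`: per-pixel binary Shannon entropy
     `H = −Σ_j p_j log₂ p_j` of foreground occupancy, min–max scaled to
     [0, 255]
   - active energy image `AEI(x,y) = (1/(N−1)) Σ_t |F_t − F_{t−1}|`
4. **Template fusion** — batch gradient descent fits nonnegative weights
   summing to one so that `w₁·GEI + w₂·GEnI + w₃·AEI` best reconstructs a
   target image (default: the per-pixel maximum of the three); the result
   is the fused energy image (**FEI**), one per cycle.
5. **Classification** — a lightweight dual-branch network: a shared
   MobileNetV2-style backbone feeds a convolutional branch and a parallel
   attention branch `F2 = M_c(F) ⊗ M_s(F) ⊗ F` (channel attention from a
   shared MLP over global average/max pooling; spatial attention from a
   depthwise-separable 7×7 convolution), fused by elementwise sum into a
   depthwise-separable-convolution head. ~3.01 M trainable parameters at
   256×256 input, ~2.89 M at 224×224.
6. **Evaluation** — confusion matrices and accuracy, macro precision,
   sensitivity, specificity and F1.

Because clinical gait video is private, the package ships a seeded
**synthetic walker generator**: parametric side-view silhouettes with known
gait period, ground-truth trough indices, and five class styles that
caricature the clinical gait descriptions. Every pipeline stage is testable
against that ground truth. The whole stack — including the network's
forward and backward passes — runs on numpy; no GPU framework is required.

## Worked example

```bash
python examples/02_templates_and_fusion.py
```

```
GEI  range [   0.0,  255.0] mean of nonzero pixels  153.1
GEnI range [   0.0,  255.0] mean of nonzero pixels  214.0
AEI  range [   0.0,  102.0] mean of nonzero pixels   71.4

BGD fusion weights (GEI, GEnI, AEI): [0.5197 0.3619 0.1184]
converged in 59 iterations, cost 1131.85 (restart 1 won)
FEI  range [0.0, 186.2]
```

One synthetic gait cycle is summarized by its three templates: the GEI
keeps the static torso bright, the GEnI highlights only the moving limbs,
the AEI is nonzero only where consecutive frames differ. Gradient descent
then finds the convex weights (here ≈ 0.52/0.36/0.12) whose template
mixture best reconstructs the per-pixel-maximum target; the weighted sum is
the FEI fed to the classifier. Other examples generate walkers and inspect
trough detection (`01`), probe the attention block's identities (`03`),
audit the parameter budget (`04`), and train the classifier end-to-end on
synthetic data (`05`, prints the confusion matrix and macro metrics; the
reduced demo reaches 90% test accuracy in about two minutes, the full
40-cycle-per-class benchmark ~97%).

A thin CLI wraps the same functions:

```bash
gait synth --n-per-class 2 --out walks --seed 1
gait cycles --in walks/festinating_000 --report cycles.json
gait model --input-size 256 --summary
gait run --out runs/demo --seed 1      # full pipeline into one run directory
```

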