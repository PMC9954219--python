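# Methods

## The operational layer

The package's core primitive is the Q-order operational convolution. Each
connection applies a polynomial nodal operator
Ψ(w, y) = Σ_{q=1..Q} w_q (y − a)^q before channel summation, so an
operational layer with weight bank W ∈ R^{C_out × C_in × Q × k × k}
computes, for output channel k,

    o_k = b_k + Σ_{i,q} corr((x_i − a)^q, W[k, i, q]).

Assumptions and conventions:

- **Constant term.** The zeroth polynomial coefficient is not stored per
  connection; it is absorbed into the per-channel bias. A per-connection
  constant is unidentifiable next to the layer bias and would only inflate
  the parameter count.
- **Shift a.** Fixed to 0 throughout, which is exact under tanh
  activations (they centre activations at the origin and bound them in
  [−1, 1], keeping the powers well-scaled). The field is stored for
  generality.
- **Orientation.** Cross-correlation, no kernel flip — the convention of
  mainstream frameworks, so serialized weights are unambiguous.
- **Padding.** Same-padding (zero-pad 1 for 3×3 kernels). The pooling
  arithmetic that yields the 512-feature flatten (224 → 112 → 56 → 28 →
  14 → 4) requires operational layers to preserve spatial size.
- **Initialization.** Symmetric uniform with fan-in scaling,
  U(−1/√(C_in·k²), +1/√(C_in·k²)), the same bound applied independently to
  each q-slice; at Q = 1 this is exactly a standard convolution
  initialization. Biases start at zero. All initialization is seeded.
- **Gradients.** Backward passes are hand-derived (im2col convolution
  adjoints plus the chain rule through the power maps,
  d(x−a)^q/dx = q(x−a)^{q−1}) and verified against central finite
  differences to < 1e−3 relative error in the test suite. The first layer
  of a stack skips its input gradient, which is never needed.

Numerical notes: layers default to float32 (adequate for training and
fast on CPU BLAS); tests that compare against analytic oracles build
float64 layers. Max pooling uses floor output arithmetic (no ceil mode);
ties inside a pooling window resolve to the first maximum in row-major
order. The final 3×3 pool uses stride 3 (14 → 4 by floor division).

## Architecture family

The default MBINet resolves the architecture's two consistent readings as
seven operational layers with channel schedule (8, 8, 8, 8, 8, 16, 32); an
alternative `enum8` preset (8, 8, 8, 8, 8, 16, 16, 32) — also consistent
with a 512 flatten — is selectable in configuration. 2×2 stride-2 pools
follow layers 1, 3, 5 and 7, a 3×3 stride-3 pool precedes the flatten, and
the head is a dense 512 → 6 map under SoftMax.

Variant topologies (4- and 6-layer models) are not fully specified
anywhere, so they reuse the MBINet schedule truncated to the stated depth
— (8, 8, 8, 8) with pools after layers 1 and 3, and (8, 8, 8, 8, 8, 16)
with pools after 1, 3 and 5 — which keeps every variant's flatten at a few
hundred features or more. The "1DN" suffix adds one hidden dense layer
(64 units, tanh, configurable) before the class head. Vanilla CNN variants
are the same graphs with Q forced to 1.

**Scaled inputs.** When the input is smaller than the reference 224×224,
the 2×2 pool stages apply in order only while the spatial size entering
the final pool stays ≥ 12. At 224 this selects exactly the canonical
schedule; at 64 it keeps two pool stages and a 5×5×32 = 800-feature
flatten instead of pooling the map down to a near-scalar 1×1 summary. The
architecture is defined by its flatten budget, and collapsing it at small
inputs would bottleneck the classifier for no reason.

## Data pipeline

Images are loaded from one folder per class, scaled to [0, 1], resized
bilinearly with centre-aligned coordinates ((j + 0.5)·scale − 0.5), and
z-score normalized per channel in storage order R, G, B. Downscaling
applies the standard Gaussian anti-alias prefilter (small tumour
boundaries must average rather than alias); upscaling is pure bilinear.
The default normalization statistics are the dataset-wide channel means
(0.2552, 0.4666, 0.8804) and standard deviations (0.4116, 0.3645, 0.2597)
on the [0, 1] pixel scale; `NormalizationStats.from_images` computes
pooled statistics when a different image source (e.g. the synthetic
generator) is used.

**Augmentation** is a fixed, deterministic ten-transform menu — rotations
±30° and ±10°, magnifications 1.10 and 1.12 (centre crop back),
translations (10%, 10%), (8%, 12%), (−10%, −10%) with zero border fill,
and a vertical flip — so each original yields exactly ten augmented
images (1,320 originals → 13,200). The exact composition of the menu is
not published; the ten entries here are drawn from the documented
parameter bands (rotation 10–40°, magnification 10–12%, translation
8–15%) and fixed once. Policy validation admits translation magnitudes
down to 8% because the published examples include an 8% horizontal shift.
Augmentation applies to the **training split only**; a `paper_faithful`
style 10×-of-total expansion (which would let augmented copies of test
images into training) is deliberately not the default, since test-set
augmentation leakage would invalidate evaluation. Augmented counts per
fold therefore differ from a 10×-of-total tally by design.

**Fold planning** stratifies by class: a seeded shuffle, contiguous
k-chunks as per-fold test sets (remainders round-robin to the first
folds), then ceil(0.2 × remainder) validation indices per class. The
ceiling rule is adopted because it reproduces the reference per-class
validation cells exactly (e.g. BT: ceil(0.2·172) = 35; totals 264 test /
213 validation per fold on class counts 300, 215, 215, 200, 200, 190).
The published narration also mentions 231 validation images in one place;
213 is the value consistent with the per-class arithmetic and is the one
this planner reproduces.

## Synthetic phantom generator

The generator renders statistical look-alikes of reconstructed microwave
head images: an elliptical head region (radius 0.38–0.45 of the image
width, soft boundary, clipped low-amplitude interior texture with
sd 0.02) on a dark background, colored through a heat-map palette with
strictly monotone luminance, plus 0–2 bright tumour blobs (intensity
0.78–0.95 vs. head level 0.35, Gaussian-softened edges). Class identity is
encoded exactly as the six classes are defined: blob count and shape
regularity. Benign blobs are regular ellipses (axis ratio 0.9–1.0) whose
measured circularity 4πA/P² is at least `benign_circularity_min` (0.85);
malignant blobs are radially perturbed polygons whose perturbation
amplitude is increased until the measured circularity falls below
`malignant_circularity_max` (0.70), so they sit just under that ceiling.
Vertex radii are clipped to [0.3, 1.15]× the nominal radius — deepening
notches rather than growing spikes — so blobs never stray past their
placement margin inside the head. Blob centres are drawn jointly with a
mutual-separation constraint (bounded retries; a `PlacementError` reports
genuinely infeasible geometry).

Two practical floors: blob radii are floored at 4.5 px, below which
shape irregularity does not rasterize (binding only for canvases smaller
than ~112 px, and applied to both shape families so absolute size never
becomes a class cue), and the canvas must be at least 48 px for two-blob
placement to remain feasible. The intended use is generation at the
native 224 px and downscaling through the pipeline's resize.

The generator is **learnable by construction**: a rule oracle (luminance
threshold at the palette image of scalar 0.6 → connected components →
count + circularity against the midpoint of the benign/malignant band)
recovers ≥ 99% of labels at default parameters, and narrowing the
circularity band degrades the oracle measurably, which makes task
difficulty controllable. What the generator does *not* model: antenna
physics, image reconstruction artifacts, inter-subject anatomy, intensity
calibration of real reconstructions, or class-correlated confounds.
Passing tests on synthetic data therefore demonstrate that the pipeline
and optimizer work end to end on a task with the right structure — not
that the classifier reaches any particular accuracy on real microwave
images.

## Training and evaluation

Defaults are the reference settings: Adam at learning rate 5e-4, batch
size 16, at most 30 epochs, early stopping on validation loss with
patience 5, plateau learning-rate factor 0.2. Interpretations of the
under-specified parts, fixed here: the loss is categorical cross-entropy
on the SoftMax outputs (standard for this head; the loss is not named in
the protocol); "loss remained constant" means no improvement > 1e−4 for
five consecutive epochs; the factor 0.2 is a reduce-on-plateau multiplier
with the plateau window equal to the patience; and a hard floor of 10
epochs applies before early stopping may trigger — a plateau reached
earlier reduces the learning rate instead of stopping. The parameters
with the best validation loss are restored after training. Non-finite
losses raise a divergence error naming the epoch.

Evaluation reduces the 6×6 confusion matrix one-vs-rest per class:
accuracy (TP+TN)/total, recall TP/(TP+FN), specificity TN/(FP+TN),
precision TP/(TP+FP), F1 2TP/(2TP+FN+FP), aggregated by support-weighted
means; overall accuracy is trace/total. Classes with zero support are
excluded from the weighting with a warning. ROC curves are one-vs-rest
per class; the single summary AUC micro-averages the flattened
one-vs-rest problem (macro averaging is available by flag) — the
averaging scheme behind the published single-number AUCs is not stated,
and micro is the default here because it weights classes by support like
the other reported metrics. Printed percentages round half-up to two
decimals. Fold aggregation reports mean and *sample* standard deviation
(ddof = 1). The misclassification audit inverts printed per-class recall
percentages into integer error counts via round-half-up.

## Desk-scale problem sizes

The test suite's end-to-end run — its scale chosen as the package's
standard desk-scale benchmark — renders 60 phantoms per class for
training and 20 per class held out, at native 224 px, scaled to a 64×64
model input; the training split (48 per class after the validation
carve-out) is expanded by the ten-transform menu to 11× and trained with
the default schedule. The cross-validation CLI smoke run uses 15 images
per class at a 32×32 input for two epochs, checking artifact emission
rather than accuracy.

## Known limitations

- The engine is CPU-numpy; it is adequate for the ~30k-parameter models
  here, not for pretrained-backbone scales (those baselines are outside
  this package's scope).
- Synthetic phantoms are statistically plausible, not physically
  calibrated; absolute accuracies on them do not transfer to real RMB
  images.
- The exact published channel enumeration of the reference architecture
  admits two readings; both are shipped, one as default (see above).
- Variant topologies beyond their operational-layer counts are invented
  plumbing and labelled as such.
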