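# mbinet

Self-organized operational neural network (Self-ONN) classification of
reconstructed microwave brain (RMB) images, in pure scientific Python.

Microwave head imaging reconstructs a 2-D intensity map of the brain from
backscattered antenna signals. Classifying those maps into six diagnostic
classes — no tumor (NT), single benign (BT), single malignant (MT), double
benign (BBT), double malignant (MMT), and one benign plus one malignant
(BMT) — is a small-data, small-compute problem that suits a lightweight
classifier. This package implements such a classifier, **MBINet**, built
from *generative neurons* rather than ordinary convolutional ones, together
with everything needed to train and evaluate it end to end: preprocessing,
deterministic augmentation, stratified five-fold cross-validation, weighted
multiclass metrics and ROC/AUC, plus a synthetic phantom-image generator so
the whole pipeline runs and is testable without the original dataset.

## The operational layer

A generative neuron replaces the fixed linear kernel product with a learned
polynomial *nodal operator*. For input activation $y$ and order $Q$,

$$\Psi(\mathbf{w}, y) \;=\; \sum_{q=1}^{Q} w_q\,(y-a)^q ,$$

the Taylor-series form of an arbitrary nonlinearity around $a$ (with $a=0$
under tanh activations, which keep inputs centred in $[-1,1]$). The output
of neuron $k$ in an operational layer is

$$o_k \;=\; b_k + \sum_{i} \Psi_{ki}(\mathbf{w}_{ki},\, y_i),$$

so each connection carries $Q$ trainable coefficients instead of one
weight; $Q=1$ recovers a standard convolution layer exactly. The constant
term of the polynomial is absorbed into the per-channel bias $b_k$.

**MBINet** stacks seven such layers (channel schedule 8, 8, 8, 8, 8, 16,
32, all 3×3 kernels, $Q=3$, tanh), with 2×2 max pooling after layers 1, 3,
5, 7 and a final 3×3 stride-3 pool. On a 224×224×3 input the spatial trace
is 224 → 112 → 56 → 28 → 14 → 4, giving a 512-feature flatten into a 6-way
SoftMax head — 28,006 trainable parameters in total. Shallower variants
(`Self-ONN4L`, `Self-ONN6L`, the `…1DN` versions with one extra hidden
dense layer) and their vanilla-CNN twins ($Q$ forced to 1) are available
from the same model zoo. Forward and backward passes are implemented
directly in numpy; gradients are exact and verified against central finite
differences in the test suite.

## Worked example

```bash
python examples/02_build_mbinet.py
```

prints the shape trace and parameter accounting of the default model:

```
default MBINet stage trace (224x224x3 input):
  input            (3, 224, 224)
  operational[1]   (8, 224, 224)
  maxpool[2]       (8, 112, 112)
  ...
  maxpool[12]      (32, 4, 4)
  flatten[13]      (512,)
  dense[14]        (6,)

trainable parameters: 28,006 (seven Q=3 operational layers + a 512->6 SoftMax head)
output probabilities (sum 1.000000):
  0.168  0.168  0.168  0.161  0.161  0.174
```

The 512-feature flatten and the probability head are the two structural
invariants of the architecture; an untrained model emits near-uniform class
probabilities. `examples/01_operational_layer.py` demonstrates the nodal
operator itself (and shows the $Q=1$ reduction agreeing with plain
cross-correlation to machine precision), `03_synthetic_phantoms.py` renders
labeled phantoms and recovers their classes with a threshold + shape rule,
`04_fold_plan_and_augmentation.py` reproduces the reference split
arithmetic (264 test / 213 validation images per fold from class counts
300, 215, 215, 200, 200, 190; ten augmentation transforms expand 1,320
originals to 13,200 training images), and `05_train_and_evaluate.py` trains
a small model and prints its weighted metrics.

A thin CLI wraps the same functions for shell use:

```bash
mbinet synth --out data/ --per-class 10 --seed 1     # synthetic dataset
mbinet split --dry-run                               # split arithmetic
mbinet crossval --per-class 30 --input-size 64 --out runs/cv --seed 1
```

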