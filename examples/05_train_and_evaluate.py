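"""Training a small classifier on synthetic phantoms and evaluating it.

Renders a modest dataset, trains MBINet at a 48x48 input for a few epochs,
and prints the weighted metrics and micro-average AUC.  (Desk-scale demo;
accuracy improves substantially with more images, a 64x64 input, the full
30-epoch schedule and the 10x augmentation menu - see the test suite's
end-to-end run.)
"""

import numpy as np

from mbinet import (
    Hyperparams,
    NormalizationStats,
    PhantomParams,
    build_variant,
    class_metrics,
    confusion_matrix,
    generate_arrays,
    resize_image,
    roc_auc,
    train_model,
    zscore_normalize,
)

SIZE = 48
images, labels, _ = generate_arrays(25, PhantomParams(), seed=11)
small = [resize_image(im, (SIZE, SIZE)) for im in images]
stats = NormalizationStats.from_images(small)
x = np.stack(
    [np.transpose(zscore_normalize(im, stats), (2, 0, 1)) for im in small]
).astype(np.float32)

rng = np.random.default_rng(0)
train_idx, val_idx, test_idx = [], [], []
for c in range(6):
    ci = rng.permutation(np.flatnonzero(labels == c))
    test_idx += list(ci[:5])
    val_idx += list(ci[5:9])
    train_idx += list(ci[9:])
train_idx, val_idx, test_idx = map(np.array, (train_idx, val_idx, test_idx))

model = build_variant("MBINet", input_size=(SIZE, SIZE, 3), seed=0)
hp = Hyperparams(max_epochs=10, min_epochs=10, seed=0)
model, hist = train_model(model, x[train_idx], labels[train_idx],
                          x[val_idx], labels[val_idx], hp)
print(f"trained {hist.epochs_run} epochs (stop: {hist.stop_reason}); "
      f"final val accuracy {hist.val_acc[-1]:.2f}")

scores = model.predict_proba(x[test_idx])
cm = confusion_matrix(labels[test_idx], scores.argmax(axis=1))
report = class_metrics(cm)
print("\nconfusion matrix (rows true, cols predicted):")
print(cm.to_frame())
print("\nweighted metrics:")
for k, v in report.weighted.items():
    print(f"  {k:12s} {v:.3f}")
_, auc = roc_auc(scores, labels[test_idx])
print(f"  micro-average AUC: {auc:.3f}")
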