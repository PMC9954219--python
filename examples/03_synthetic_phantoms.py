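"""Generating synthetic phantom images and recovering their labels.

Renders a handful of head phantoms per diagnostic class and shows that a
simple threshold + shape rule recovers the class, i.e. the generated task
is learnable by construction.
"""

import numpy as np

from mbinet import ClassLabel, PhantomParams, generate_arrays, generate_image, rule_based_label

params = PhantomParams()  # 224x224, default circularity band 0.85 / 0.70

img, gt = generate_image(ClassLabel.BMT, params, rng=7)
print("one BMT phantom (single benign + single malignant):")
for t in gt.tumors:
    print(f"  {t.kind:9s} at ({t.center[0]:6.1f}, {t.center[1]:6.1f}), "
          f"equivalent radius {t.radius:4.1f}px, circularity {t.circularity:.2f}")

images, labels, _ = generate_arrays(5, params, seed=42)
preds = [rule_based_label(im, params) for im in images]
acc = np.mean([p == l for p, l in zip(preds, labels)])
print(f"\nrule-based oracle accuracy on 30 phantoms (5 per class): {acc:.0%}")
print("-> benign blobs are round (circularity >= 0.85), malignant blobs "
      "irregular (< 0.70); the count + shape rule separates all six classes.")
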