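"""Stratified five-fold splitting and the fixed ten-transform augmentation.

Reproduces the reference split arithmetic on the published class counts and
shows the tenfold training-set expansion.
"""

import numpy as np

from mbinet import apply_augmentation, build_fold_plan, default_augmentation_menu
from mbinet.data import LabeledImage
from mbinet.labels import CLASS_NAMES

counts = dict(zip(CLASS_NAMES, (300, 215, 215, 200, 200, 190)))
labels = np.repeat(np.arange(6), list(counts.values()))
plan = build_fold_plan(labels, k=5, val_frac=0.2, seed=0)

sizes = plan.split_counts()
print(f"dataset: {len(labels)} images, classes {counts}")
print(f"per-fold sizes: train {sizes['train'][0]}, "
      f"validation {sizes['validation'][0]}, test {sizes['test'][0]}")
print("fold-0 validation per class:", plan.class_counts(0, "validation"))

menu = default_augmentation_menu()
print(f"\naugmentation menu ({len(menu)} deterministic transforms):")
for tf in menu:
    print("  ", tf)

img = LabeledImage(np.random.default_rng(0).uniform(size=(64, 64, 3)), 0, "demo")
out = apply_augmentation(img, menu)
print(f"\n1 original -> {len(out)} augmented images; "
      f"{len(labels)} originals -> {len(labels) * len(menu)} training images")
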