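"""Constructing MBINet and tracing its shape arithmetic.

Prints the spatial pipeline of the default configuration, its parameter
count, and the model-zoo variants.
"""

import numpy as np

from mbinet import build_variant, count_parameters, mbinet_config, trace_shapes
from mbinet.architectures import MODEL_NAMES, count_operational_layers

cfg = mbinet_config()
print("default MBINet stage trace (224x224x3 input):")
for stage, shape in trace_shapes(cfg):
    print(f"  {stage:16s} {shape}")

model = build_variant("MBINet", seed=0)
print(f"\ntrainable parameters: {count_parameters(model):,} "
      "(seven Q=3 operational layers + a 512->6 SoftMax head)")

x = np.random.default_rng(0).normal(size=(1, 3, 224, 224)).astype(np.float32)
probs = model.predict_proba(x)
print(f"output probabilities (sum {probs.sum():.6f}):")
print("  " + "  ".join(f"{p:.3f}" for p in probs[0]))

print("\nmodel zoo (64x64 input):")
for name in MODEL_NAMES:
    m = build_variant(name, seed=0, input_size=(64, 64, 3))
    print(f"  {name:15s} {count_operational_layers(m)} operational layers, "
          f"{count_parameters(m):7,} parameters")
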