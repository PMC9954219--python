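"""The generative-neuron layer: polynomial nodal operators vs. convolution.

Builds a tiny Q=3 operational layer, shows that the Q=1 special case is an
ordinary convolution, and evaluates the nodal polynomial directly.
"""

import numpy as np
from scipy.signal import correlate2d

from mbinet import NodalWeights, OperationalLayerParams, nodal_transform, operational_conv2d

rng = np.random.default_rng(0)

# A nodal operator Psi(w, y) = w1 y + w2 y^2 + w3 y^3 applied to one value.
w = NodalWeights([0.8, -0.3, 0.1])
y = 0.5
print(f"Psi({y}) = {nodal_transform(y, w):+.5f}   (w1 y + w2 y^2 + w3 y^3)")

# A Q=3 operational layer mixes three power maps of the input per kernel tap.
x = rng.normal(size=(1, 7, 7))
weights = rng.normal(size=(1, 1, 3, 3, 3)) * 0.2
params = OperationalLayerParams(weights, bias=np.zeros(1), q_order=3)
out = operational_conv2d(x, params)
print(f"Q=3 layer output: shape {out.shape}, mean {out.mean():+.4f}")

# With Q=1 the same machinery is exactly a standard convolution layer.
w1 = weights[:, :, :1]
out_q1 = operational_conv2d(x, OperationalLayerParams(w1, np.zeros(1), 1))
ref = correlate2d(x[0], w1[0, 0, 0], mode="same")
print(f"Q=1 vs plain cross-correlation, max |difference|: "
      f"{np.abs(out_q1[0] - ref).max():.2e}")
print("-> the operational layer generalizes convolution; Q controls the "
      "per-connection polynomial degree (and parameter count).")
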