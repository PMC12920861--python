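"""Encode keypoints as Gaussian heatmaps and decode them back.

The pose estimator does not regress coordinates directly: each keypoint
becomes one heatmap channel holding an unnormalized Gaussian (peak 1 at
the keypoint, sigma 20 px at 224x224). Training minimizes a weighted MSE
that up-weights the LV/RV channels (1.2 vs 1.0), and prediction reads
the per-channel argmax.
"""

import numpy as np

from vfpose import (
    ChannelWeights,
    Keypoint,
    KeypointTriplet,
    decode_heatmaps,
    encode_heatmaps,
    wmse_loss,
)

triplet = KeypointTriplet(
    LV=Keypoint(130, 150), RV=Keypoint(95, 148), A=Keypoint(112, 60)
)
stack = encode_heatmaps(triplet, height=224, width=224, sigma=20)
print(f"heatmap stack shape {stack.shape}, peak value {stack.max():.1f}")

decoded = decode_heatmaps(stack)
print(f"decoded LV back at ({decoded.LV.x:.0f}, {decoded.LV.y:.0f})"
      " — exact for integer keypoints")

# the W-MSE loss between the clean stack and a noisy prediction
noisy = np.clip(stack + np.random.default_rng(0).normal(0, 0.05, stack.shape), 0, 1)
loss = wmse_loss(noisy, stack, ChannelWeights())
print(f"W-MSE(noisy, clean) = {loss:.5f}  (0 for a perfect prediction)")
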