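"""Detect scale-space keypoints on a synthetic blob image.

Builds an image containing one bright Gaussian blob, constructs the DoG
pyramid and prints the detected keypoints.  The strongest keypoint should
sit near the blob centre (32, 32) with a characteristic scale close to
blob_sigma * sqrt(2) ~ 5.7 px — the scale at which the DoG response of a
blob peaks.
"""

import numpy as np

from endostitch import build_scale_space, detect_extrema

size, blob_sigma = 64, 4.0
yy, xx = np.mgrid[0:size, 0:size].astype(float)
img = 0.1 + 0.6 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * blob_sigma**2))

ss = build_scale_space(img, n_octaves=3, s=3, sigma0=1.6)
keypoints = detect_extrema(ss, contrast_thresh=0.03, edge_ratio=10.0)

print(f"{len(keypoints)} keypoint(s) detected")
for kp in sorted(keypoints, key=lambda k: -abs(k.response)):
    print(
        f"  x={kp.x:6.2f}  y={kp.y:6.2f}  sigma={kp.sigma:5.2f}  "
        f"response={kp.response:+.4f}  octave={kp.octave}"
    )
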