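"""Crop a photograph to its foreground object.

Simulates a photo-sized canvas with one small bright object on a dark
stage, then extracts the foreground, finds its minimum enclosing circle
and crops to it — the shrink step applied to raw images before annotation.
"""

import numpy as np

from shredcot import preprocess_image

image = np.zeros((2748, 3840), dtype=np.uint8)
image[1200:1500, 1800:1900] = 200  # a 300 x 100 px object

cropped, foreground, circle = preprocess_image(image, pad=10)

print(f"foreground area : {int(foreground.sum())} px")
print(f"enclosing circle: center=({circle.center[0]:.1f}, {circle.center[1]:.1f}) "
      f"r={circle.radius:.1f}")
print(f"crop            : {image.shape} -> {cropped.shape} "
      f"({100 * cropped.size / image.size:.2f}% of original)")
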