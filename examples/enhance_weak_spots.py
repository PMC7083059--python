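"""Enhance weak protein spots in a single synthetic gel with GIHE.

Renders a 2DE-like gel, equalizes it against its gradient interval
histogram, and reports (a) the gray-level interval where contrast is
stretched (equalization slope > 1, i.e. p(k) > 1/255) and (b) the mean
center-minus-background gray difference of the weak spots before and
after enhancement.  A more negative difference means the weak spots
stand out more from the background.
"""

import numpy as np

from gih2de import GrayImage, SpotRecord, gihe, gray_value_difference
from gih2de.synthetic import GelSpec, render_gel

spec = GelSpec.random(seed=1)
img, truth = render_gel(spec)
result = gihe(img)

stretched = np.flatnonzero(result.distribution.pdf > 1 / 255.0)
print(f"contrast stretched on gray levels {stretched.min()}..{stretched.max()}")

diffs_before, diffs_after = [], []
for s in truth.spots:
    if not s.is_weak:
        continue
    # center = darkest pixel of the support; local background = ring
    vals = img.pixels[s.support[:, 0], s.support[:, 1]]
    center = s.support[np.argmin(vals)][None, :]
    mask = np.zeros(img.shape, dtype=bool)
    mask[s.support[:, 0], s.support[:, 1]] = True
    from scipy import ndimage as ndi

    ring = np.argwhere(ndi.binary_dilation(mask, iterations=3) & ~mask)
    for image, sink in ((img, diffs_before), (result.image, diffs_after)):
        spot = SpotRecord.measure(image, s.spot_id, center, s.support, ring)
        sink.append(gray_value_difference(image, spot))

print(f"mean weak-spot gray difference before GIHE: {np.mean(diffs_before):8.2f}")
print(f"mean weak-spot gray difference after  GIHE: {np.mean(diffs_after):8.2f}")
print("(more negative = weak spots darker than their local background)")
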