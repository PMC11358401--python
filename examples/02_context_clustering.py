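"""Context labeling: k-means over intensities for k = 4..9.

The non-hypothalamic tissue only conditions synthetic image contrast,
so unsupervised intensity clusters suffice; running all six k values
multiplies the label-map variability available for training.
"""

import numpy as np

from hemilabel import (
    ContextSetConfig,
    PhantomSpec,
    generate_context_set,
    make_phantom_hemisphere,
    mask_background,
)

vol, _ = make_phantom_hemisphere(PhantomSpec(shape=(64, 64, 64), seed=1))
mask = mask_background(vol)
maps = generate_context_set(vol, mask, ContextSetConfig(seed=1))

print(f"{len(maps)} context maps from one volume (k = 4..9):")
for k, lm in zip(range(4, 10), maps):
    ids = [int(i) for i in lm.ids() if i > 100]
    means = [float(vol.data[lm.data == i].mean()) for i in ids]
    print(f"  k={k}: ids {ids[0]}..{ids[-1]}, cluster means "
          + " < ".join(f"{m:.0f}" for m in means))
print("Ids are sorted by ascending mean intensity (first id = darkest),")
print("offset by 100 so they never collide with subregion ids 1-10.")
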