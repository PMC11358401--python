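"""Synthetic training data: random contrast, geometry and resolution.

Each draw augments the full-brain label map geometrically, samples a
random Gaussian intensity model per label, and simulates a lower
acquisition resolution -- so a segmenter trained on these pairs never
sees the same contrast twice.
"""

import numpy as np

from hemilabel import SynthConfig, generate_training_pair, sample_gmm_image
from hemilabel.core import LabelMap

# a small synthetic full-brain map (ids 1-10 + two context classes)
data = np.zeros((48, 48, 48), dtype=np.int32)
data[2:24, 4:44, 4:44] = 101
data[24:46, 4:44, 4:44] = 102
for i, sid in enumerate(range(1, 6)):
    data[18:24, 8 + 6 * i: 13 + 6 * i, 18:30] = sid
    data[24:30, 8 + 6 * i: 13 + 6 * i, 18:30] = sid + 5
full = LabelMap(data, np.diag([0.3, 0.3, 0.3, 1.0]))

image, draw = sample_gmm_image(full, SynthConfig(), seed=0)
print("drawn intensity model (label: mean, std):")
for lid in sorted(draw.means):
    print(f"  {lid:>3}: mu={draw.means[lid]:6.1f}  sigma={draw.stds[lid]:5.1f}")

# augmentation ranges scaled to this small demo volume (14 mm field of view)
cfg = SynthConfig(translation_range=1.5, elastic_scale=0.5, thickness_range=(0.3, 2.0))
for seed in range(3):
    img, target = generate_training_pair(full, cfg, seed=seed)
    tids = sorted(int(i) for i in target.ids())
    print(f"pair seed {seed}: image in [{img.data.min():.2f}, {img.data.max():.2f}], "
          f"target ids {tids}")
print("Targets keep only ids 0-10: context classes shape the image")
print("appearance but are never segmentation targets.")
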