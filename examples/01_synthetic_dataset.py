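"""Generate a synthetic blood-smear dataset and check class separability.

Renders two-class smear-like RGB images (healthy: few small round nuclei;
diseased: more, larger, lobed nuclei), writes them in the folder-per-class
layout, and shows that the stained-pixel fraction alone already separates
the classes — the floor any image classifier should clear.
"""

import numpy as np

from smearopt import SmearParams, generate_dataset, stained_fraction
from smearopt.data import DISEASED, HEALTHY, write_image_folder

params = SmearParams().for_size(128)
bundle = generate_dataset(n_healthy=40, n_diseased=40, params=params, seed=7)
write_image_folder(bundle, "scratch/synthetic_demo")

frac = {
    label: np.mean([
        stained_fraction(im.pixels) for im in bundle.images if im.label == label
    ])
    for label in (HEALTHY, DISEASED)
}
print(f"images written: {len(bundle)} -> scratch/synthetic_demo/")
print(f"mean stained-pixel fraction, healthy : {frac[HEALTHY]:.4f}")
print(f"mean stained-pixel fraction, diseased: {frac[DISEASED]:.4f}")
print("diseased frames carry several-fold more nuclear stain, so the two")
print("classes are separable before any network is trained.")
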