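"""Dataset arithmetic of the hybrid two-source smear corpus.

Merges two class-labeled image sets with the compositions of the public
ALL-IDB1 (59 healthy + 49 diseased) and ALL-IDB2 (130 + 130) subsets,
applies the six-fold augmentation (identity, two reflections, rotations
by 90 and +/-45 degrees) and the 80/10/10 split, and prints the resulting
counts at each stage.
"""

import numpy as np

from smearopt.data import (
    DISEASED,
    HEALTHY,
    DatasetBundle,
    LabeledImage,
    augment,
    merge_datasets,
    split_dataset,
)

rng = np.random.default_rng(0)


def stand_in(n_healthy, n_diseased, tag):
    # synthetic stand-in pixels; only the counts matter here
    return DatasetBundle([
        LabeledImage(rng.integers(0, 256, (16, 16, 3), dtype=np.uint8),
                     label, f"{tag}_{label}_{i}")
        for label, n in ((HEALTHY, n_healthy), (DISEASED, n_diseased))
        for i in range(n)
    ])


hybrid = merge_datasets(stand_in(59, 49, "set1"), stand_in(130, 130, "set2"))
print(f"hybrid set: {len(hybrid)} images {hybrid.class_counts()}")

enlarged = augment(hybrid)
print(f"after 6-fold augmentation: {len(enlarged)} images "
      f"{enlarged.class_counts()}")

split = split_dataset(enlarged, fractions=(0.8, 0.1, 0.1), seed=0)
sizes = {k: len(v) for k, v in split.partitions.items()}
print(f"80/10/10 split: {sizes}")
print("every image is used exactly once; validation and test take the")
print("floor of 10% each and the remainder trains.")
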