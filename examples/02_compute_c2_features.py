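"""Run the full feature hierarchy on a few images: Gabor S1 maps, pooled C1
maps, a random patch pool, and the C2 feature vectors used for
classification.

Run:  python examples/02_compute_c2_features.py
"""

import numpy as np

from hmaxga import (
    FixtureSpec,
    batch_c2,
    build_filter_bank,
    compute_c1,
    extract_patches,
    generate_dataset,
)

bank = build_filter_bank()
print(f"filter bank: {len(bank.kernels)} Gabor kernels "
      f"({len(bank.sizes)} sizes {bank.sizes[0]}..{bank.sizes[-1]}, "
      f"{len(bank.thetas)} orientations), {bank.n_bands} scale bands")

dataset, _ = generate_dataset(FixtureSpec(n_pos=3, n_neg=3, seed=4))
c1s = [compute_c1(img, bank, source_id=i)
       for img, i in zip(dataset.images, dataset.ids)]
print(f"C1: {c1s[0].n_maps} maps per image; band 2 grid = "
      f"{c1s[0].band(2).shape[1:]} cells")

# patch pool from the target images only (size-major order)
targets = [c1 for c1 in c1s if c1.source_id.startswith("pos")]
pdict = extract_patches(targets, sizes=(4, 8), count_per_size=10, seed=0)
print(f"patch pool: {len(pdict)} prototypes, counts by size "
      f"{pdict.size_counts()}")

matrix = batch_c2(c1s, pdict)
print(f"C2 matrix: {matrix.values.shape[0]} patches x "
      f"{matrix.values.shape[1]} images, values in "
      f"({matrix.values.min():.3f}, {matrix.values.max():.3f}]")
# Each entry is exp(-d^2 / 2 sigma^2) of the best match of one prototype
# anywhere in one image; 1.0 means the prototype was found verbatim.
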