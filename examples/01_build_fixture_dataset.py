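"""Generate the synthetic two-class dataset: a planted oriented-bar motif in
clutter (targets) versus clutter alone (backgrounds).

Run:  python examples/01_build_fixture_dataset.py
"""

import numpy as np

from hmaxga import FixtureSpec, generate_dataset

spec = FixtureSpec(n_pos=5, n_neg=5, seed=0)
dataset, boxes = generate_dataset(spec)

print(f"{len(dataset)} images of {spec.height}x{spec.width} px, "
      f"{int((dataset.labels == 1).sum())} targets / "
      f"{int((dataset.labels == -1).sum())} backgrounds")
for img_id in dataset.ids[:3]:
    box = boxes[img_id]
    print(f"  {img_id}: motif box = {box}")
print(f"  {dataset.ids[-1]}: motif box = {boxes[dataset.ids[-1]]}")

img = dataset.images[0]
print(f"intensities in [{img.min():.2f}, {img.max():.2f}] "
      f"(bars on dark ground plus sensor noise)")

# The boxes say where the motif is, so later stages can score whether a
# feature was learned from the object or from the clutter.
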