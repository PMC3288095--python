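"""Random patch (prototype) extraction from C1 activations.

A patch of side n holds an n x n x 4 block of C1 activations (all four
orientation channels at one position of one scale band).  The pool is drawn
at uniformly random positions from uniformly random training images,
band 2 only, size-major order, reproducibly from a seed.  Patches are stored
raw (no normalization); duplicates are allowed - discarding redundant ones is
the selection stage's job.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .c1 import C1Maps

DEFAULT_SIZES = (4, 8, 12, 16)
DEFAULT_BAND = 2


@dataclass
class Patch:
    """One prototype: values shaped (4, n, n) = orientation channels first."""

    id: str
    values: np.ndarray
    size_n: int
    source_image: str
    position: tuple  # (row, col) in the source C1 band map
    band: int = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.size_n
        if self.values.shape != (4, n, n):
            raise ValueError(f"patch values must be (4, {n}, {n}), "
                             f"got {self.values.shape}")
        if not np.isfinite(self.values).all() or self.values.min() < 0:
            raise ValueError("patch values must be finite and >= 0")

    @property
    def n_elements(self) -> int:
        return self.values.size


@dataclass
class PatchDictionary:
    """Ordered pool of prototypes, reproducible from its extraction seed."""

    patches: list
    extraction_seed: int

    def __post_init__(self) -> None:
        if len(self.patches) < 1:
            raise ValueError("a patch dictionary needs at least one patch")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def sizes(self) -> tuple:
        return tuple(sorted({p.size_n for p in self.patches}))

    def size_counts(self) -> dict:
        counts = {n: 0 for n in self.sizes}
        for p in self.patches:
            counts[p.size_n] += 1
        return counts


def extract_patches(
    train: Sequence[C1Maps],
    sizes: Sequence[int] = DEFAULT_SIZES,
    count_per_size: int = 50,
    seed: int = 0,
    band: int = DEFAULT_BAND,
) -> PatchDictionary:
    """Draw ``count_per_size`` patches per size from the training C1 stacks.

    Order is size-major, draw-order-minor; the same seed reproduces the
    dictionary exactly.
    """
    if len(train) == 0:
        raise ValueError("cannot extract patches from an empty training list")
    if count_per_size < 1:
        raise ValueError("count_per_size must be >= 1")
    sizes = [int(n) for n in sizes]
    if not sizes:
        raise ValueError("need at least one patch size")
    n_max = max(sizes)
    for k, c1 in enumerate(train):
        arr = c1.band(band)
        if min(arr.shape[1], arr.shape[2]) < n_max:
            raise ValueError(
                f"band-{band} C1 map of training image {k} is "
                f"{arr.shape[1]}x{arr.shape[2]}, smaller than the largest "
                f"requested patch ({n_max})"
            )
    rng = np.random.default_rng(seed)
    patches = []
    pid = 0
    for n in sizes:
        for _ in range(count_per_size):
            k = int(rng.integers(len(train)))
            arr = train[k].band(band)
            h, w = arr.shape[1], arr.shape[2]
            r = int(rng.integers(h - n + 1))
            c = int(rng.integers(w - n + 1))
            source = train[k].source_id if train[k].source_id is not None else str(k)
            patches.append(
                Patch(id=f"p{pid:04d}_n{n}", values=arr[:, r:r + n, c:c + n].copy(),
                      size_n=n, source_image=source, position=(r, c), band=band)
            )
            pid += 1
    return PatchDictionary(patches=patches, extraction_seed=int(seed))


def save_dictionary(pdict: PatchDictionary, path) -> None:
    """Archive patch blocks plus metadata (NumPy .npz)."""
    meta = {
        "extraction_seed": pdict.extraction_seed,
        "ids": [p.id for p in pdict.patches],
        "sizes": [p.size_n for p in pdict.patches],
        "sources": [p.source_image for p in pdict.patches],
        "positions": [list(p.position) for p in pdict.patches],
        "bands": [p.band for p in pdict.patches],
    }
    arrays = {f"values_{i}": p.values for i, p in enumerate(pdict.patches)}
    np.savez_compressed(Path(path), meta=np.array(json.dumps(meta)), **arrays)


def load_dictionary(path) -> PatchDictionary:
    with np.load(Path(path)) as data:
        meta = json.loads(str(data["meta"]))
        patches = [
            Patch(id=meta["ids"][i], values=data[f"values_{i}"],
                  size_n=meta["sizes"][i], source_image=meta["sources"][i],
                  position=tuple(meta["positions"][i]), band=meta["bands"][i])
            for i in range(len(meta["ids"]))
        ]
    return PatchDictionary(patches=patches,
                           extraction_seed=int(meta["extraction_seed"]))


def write_manifest(pdict: PatchDictionary, path) -> None:
    """Human-readable CSV manifest (id, n, source image, row, col, band)."""
    rows = [
        {"id": p.id, "n": p.size_n, "source_image": p.source_image,
         "row": p.position[0], "col": p.position[1], "band": p.band}
        for p in pdict.patches
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
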