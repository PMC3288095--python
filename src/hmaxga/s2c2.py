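"""The S2/C2 stages: prototype matching and global max pooling.

At every valid position of every C1 scale band, S2 computes the Euclidean
distance d between a stored patch and the co-located n x n x 4 block of C1
activations, passed through Gaussian tuning exp(-d^2 / (2 sigma^2)) so that
larger means more similar.  C2 takes the global maximum over all positions
and bands, giving one scalar per patch per image - a feature vector that is
tolerant to translation and scale changes of the stimulus.

A ``min_distance`` mode skips the tuning and reports the global minimum raw
distance instead (lower = more similar).

Selection commutes with computation: the C2 vector of an active subset equals
the corresponding rows of the full-dictionary C2 vector, which makes wrapper
fitness evaluation a cheap row-masking of one precomputed matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .c1 import C1Maps
from .patches import Patch, PatchDictionary

logger = logging.getLogger(__name__)


@dataclass
class S2Config:
    """Gaussian tuning width (same units as C1 activations) and pooling mode."""

    tuning_sigma: float = 1.0
    mode: str = "gaussian"  # or "min_distance"

    def __post_init__(self) -> None:
        if self.tuning_sigma <= 0:
            raise ValueError("tuning_sigma must be positive")
        if self.mode not in ("gaussian", "min_distance"):
            raise ValueError(f"unknown S2 mode: {self.mode!r}")


class C2Matrix(NamedTuple):
    """P x K feature matrix: rows = patches, columns = images."""

    values: np.ndarray
    patch_ids: list
    image_ids: list


def _band_blocks(band_arr: np.ndarray, n: int) -> np.ndarray:
    """All n x n x 4 blocks of a (4, h, w) band map, flattened per position.

    Returns shape (n_positions, 4 * n * n); row-major position order.
    """
    win = sliding_window_view(band_arr, (n, n), axis=(1, 2))
    # (4, h', w', n, n) -> (h', w', 4, n, n) -> (h' * w', 4 n n)
    return win.transpose(1, 2, 0, 3, 4).reshape(-1, band_arr.shape[0] * n * n)


def _sq_dists(blocks: np.ndarray, flat_patches: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (n_positions, n_patches)."""
    x_sq = np.einsum("ij,ij->i", blocks, blocks)
    p_sq = np.einsum("ij,ij->i", flat_patches, flat_patches)
    d2 = x_sq[:, None] - 2.0 * (blocks @ flat_patches.T) + p_sq[None, :]
    return np.clip(d2, 0.0, None)


def s2_response_map(c1: C1Maps, patch: Patch, cfg: S2Config | None = None) -> dict:
    """Per-band S2 maps for one patch.

    Returns ``{band: 2-D map}``; bands too small for the patch are skipped
    with a logged warning.  In ``gaussian`` mode maps hold tuned similarities
    in (0, 1]; in ``min_distance`` mode, raw Euclidean distances.
    """
    cfg = cfg if cfg is not None else S2Config()
    n = patch.size_n
    flat = patch.values.reshape(1, -1)
    out = {}
    for b in range(1, c1.n_bands + 1):
        arr = c1.band(b)
        if arr.shape[1] < n or arr.shape[2] < n:
            logger.warning("patch %s (n=%d) larger than band %d map %s; "
                           "band skipped", patch.id, n, b, arr.shape[1:])
            continue
        blocks = _band_blocks(arr, n)
        d2 = _sq_dists(blocks, flat)[:, 0]
        grid = d2.reshape(arr.shape[1] - n + 1, arr.shape[2] - n + 1)
        if cfg.mode == "gaussian":
            out[b] = np.exp(-grid / (2.0 * cfg.tuning_sigma**2))
        else:
            out[b] = np.sqrt(grid)
    if not out:
        raise ValueError(f"patch {patch.id} is larger than every C1 band map")
    return out


def compute_c2(
    c1: C1Maps,
    pdict: PatchDictionary,
    active: np.ndarray | None = None,
    cfg: S2Config | None = None,
) -> np.ndarray:
    """C2 feature vector of one image for the active patches.

    The vector follows dictionary order restricted to active patches.  An
    all-zero active mask is invalid.
    """
    cfg = cfg if cfg is not None else S2Config()
    if active is None:
        active = np.ones(len(pdict), dtype=bool)
    active = np.asarray(active).astype(bool)
    if active.shape != (len(pdict),):
        raise ValueError("active mask length must equal dictionary size")
    if not active.any():
        raise ValueError("the active patch set is empty")

    idx = np.flatnonzero(active)
    by_size: dict = {}
    for pos, i in enumerate(idx):
        by_size.setdefault(pdict.patches[i].size_n, []).append((pos, i))

    best_d2 = np.full(len(idx), np.inf)
    matched = np.zeros(len(idx), dtype=bool)
    for n, entries in by_size.items():
        positions = [pos for pos, _ in entries]
        flat = np.stack([pdict.patches[i].values.reshape(-1)
                         for _, i in entries])
        for b in range(1, c1.n_bands + 1):
            arr = c1.band(b)
            if arr.shape[1] < n or arr.shape[2] < n:
                continue
            blocks = _band_blocks(arr, n)
            d2 = _sq_dists(blocks, flat).min(axis=0)
            np.minimum.at(best_d2, positions, d2)
            matched[positions] = True
    if not matched.all():
        missing = [pdict.patches[idx[k]].id for k in np.flatnonzero(~matched)]
        raise ValueError(f"patches larger than every C1 band map: {missing}")

    if cfg.mode == "gaussian":
        return np.exp(-best_d2 / (2.0 * cfg.tuning_sigma**2))
    return np.sqrt(best_d2)


def batch_c2(
    c1s: Sequence[C1Maps],
    pdict: PatchDictionary,
    active: np.ndarray | None = None,
    cfg: S2Config | None = None,
    image_ids: Sequence[str] | None = None,
) -> C2Matrix:
    """Stack per-image C2 vectors into a P x K matrix (columns = input order)."""
    if len(c1s) == 0:
        raise ValueError("batch_c2 needs at least one image")
    if image_ids is None:
        image_ids = [
            c1.source_id if c1.source_id is not None else f"img{k}"
            for k, c1 in enumerate(c1s)
        ]
    if active is None:
        active = np.ones(len(pdict), dtype=bool)
    active = np.asarray(active).astype(bool)
    cols = []
    for c1, img_id in zip(c1s, image_ids):
        try:
            cols.append(compute_c2(c1, pdict, active, cfg))
        except ValueError as exc:
            raise ValueError(f"C2 failed for image {img_id}: {exc}") from exc
    patch_ids = [pdict.patches[i].id for i in np.flatnonzero(active)]
    return C2Matrix(values=np.column_stack(cols), patch_ids=patch_ids,
                    image_ids=list(image_ids))


def dataset_c2(dataset, pdict, active=None, cfg=None, bank=None, c1_cfg=None):
    """Convenience: full image -> C1 -> C2 pipeline over a LabeledDataset."""
    from .c1 import compute_c1

    c1s = [compute_c1(img, bank=bank, cfg=c1_cfg, source_id=img_id)
           for img, img_id in zip(dataset.images, dataset.ids)]
    return batch_c2(c1s, pdict, active=active, cfg=cfg, image_ids=dataset.ids)
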