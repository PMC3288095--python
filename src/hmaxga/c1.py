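"""The C1 stage: complex-cell pooling for position and scale tolerance.

Two max-pooling steps: (1) element-wise max over the two adjacent filter
sizes of each band at the same orientation (64 S1 maps -> 32 band maps);
(2) local max over an N^Sigma x N^Sigma grid with overlap Delta_s, i.e.
stride N^Sigma - Delta_s.  Border windows are clipped (partial windows kept)
so stimuli near the edge are not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import default_config
from .s1 import FilterBank, S1Maps, apply_s1, build_filter_bank


@dataclass
class C1Config:
    """Per-band pooling grid size (N^Sigma) and overlap (Delta_s), keyed by
    band number (1-based)."""

    grid_size: dict
    overlap: dict

    def __post_init__(self) -> None:
        if set(self.grid_size) != set(self.overlap):
            raise ValueError("grid_size and overlap must cover the same bands")
        for b, n in self.grid_size.items():
            ds = self.overlap[b]
            if not 0 < ds < n:
                raise ValueError(f"band {b}: need 0 < overlap < grid size, "
                                 f"got Delta_s={ds}, N={n}")

    def stride(self, band: int) -> int:
        return self.grid_size[band] - self.overlap[band]


def default_c1_config() -> C1Config:
    c1 = default_config()["c1"]
    return C1Config(grid_size=dict(c1["grid_size"]), overlap=dict(c1["overlap"]))


@dataclass
class C1Maps:
    """Pooled maps: ``bands[b-1]`` has shape (n_orientations, h_b, w_b)."""

    bands: list
    thetas: tuple
    source_id: str | None = None

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_maps(self) -> int:
        return sum(b.shape[0] for b in self.bands)

    def band(self, band: int) -> np.ndarray:
        """1-based band accessor."""
        return self.bands[band - 1]


def pool_scales(s1: S1Maps, bank: FilterBank) -> list:
    """Element-wise max over each band's two adjacent sizes.

    Returns one (n_orientations, H, W) array per band.
    """
    out = []
    for b in sorted(bank.band_index):
        size_a, size_b = bank.band_index[b]
        try:
            ia, ib = s1.sizes.index(size_a), s1.sizes.index(size_b)
        except ValueError as exc:
            raise ValueError(f"S1 stack is missing maps for band {b} "
                             f"(sizes {size_a}, {size_b})") from exc
        out.append(np.maximum(s1.responses[ia], s1.responses[ib]))
    return out


def pool_local(m: np.ndarray, n: int, overlap: int) -> np.ndarray:
    """Max over n x n windows anchored at stride (n - overlap), clipped at
    borders.  Output dims are ceil((dim - n) / stride) + 1 per axis."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("pool_local expects a 2-D map")
    h, w = m.shape
    if n > h or n > w:
        raise ValueError(f"window size {n} exceeds map dims {m.shape}")
    if not 0 < overlap < n:
        raise ValueError("need 0 < overlap < window size")
    stride = n - overlap
    oh = math.ceil((h - n) / stride) + 1
    ow = math.ceil((w - n) / stride) + 1
    out = np.empty((oh, ow), dtype=float)
    for i in range(oh):
        r = i * stride
        for j in range(ow):
            c = j * stride
            out[i, j] = m[r:r + n, c:c + n].max()
    return out


def compute_c1(
    img: np.ndarray,
    bank: FilterBank | None = None,
    cfg: C1Config | None = None,
    source_id: str | None = None,
) -> C1Maps:
    """Full S1 -> C1 pipeline for one image (32 maps with the defaults)."""
    bank = bank if bank is not None else build_filter_bank()
    cfg = cfg if cfg is not None else default_c1_config()
    if set(cfg.grid_size) != set(bank.band_index):
        raise ValueError("C1 config bands do not match the filter bank bands")
    s1 = apply_s1(img, bank)
    banded = pool_scales(s1, bank)
    bands = []
    for b, stack in zip(sorted(bank.band_index), banded):
        n, ds = cfg.grid_size[b], cfg.overlap[b]
        pooled = np.stack([pool_local(stack[t], n, ds)
                           for t in range(stack.shape[0])])
        bands.append(pooled)
    return C1Maps(bands=bands, thetas=bank.thetas, source_id=source_id)
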