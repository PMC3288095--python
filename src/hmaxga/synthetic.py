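"""Programmatic two-class image generator: a planted oriented-bar motif in
clutter versus clutter alone.

Positive images contain exactly one "stick face" motif - two short vertical
bars (eyes), a diagonal bar (nose) and a longer horizontal bar (mouth) at
fixed relative offsets - placed at a jittered scale and position on top of
random clutter bars; negative images contain clutter only.  The motif is made
of oriented bars because the S1 stage is an oriented-edge bank, so the two
classes are discriminable at the C1 level by construction.  Ground-truth
motif bounding boxes are recorded so patch provenance can be scored as
on-motif versus clutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .c1 import C1Config, default_c1_config
from .io import LabeledDataset
from .patches import Patch


@dataclass
class FixtureSpec:
    """Generator conditions.

    Defaults give 50 target and 50 background images at 112 x 150 px with a
    motif about 40% of the image height, 14-22 clutter bars of random
    orientation and additive Gaussian sensor noise (sd 0.10) - a mid
    difficulty regime comparable to cluttered two-class benchmarks.
    """

    height: int = 112
    width: int = 150
    motif_scale: float = 46.0
    scale_jitter: float = 0.15
    margin: int = 16  # min distance of the motif box from the borders
    n_clutter: tuple = (14, 22)
    clutter_length: tuple = (10.0, 30.0)
    bar_thickness: float = 2.0
    bar_value: tuple = (0.6, 1.0)
    noise_sd: float = 0.10
    n_pos: int = 50
    n_neg: int = 50
    seed: int = 0


def draw_bar(img: np.ndarray, center, length: float, angle_deg: float,
             thickness: float, value: float) -> tuple:
    """Stamp a bar (bright line segment) onto ``img`` in place.

    ``angle_deg`` is the bar's direction measured from the column axis,
    counter-clockwise in standard (x right, y up) terms; rows grow downward.
    Returns the bar's bounding box (r0, r1, c0, c1), end-exclusive.
    """
    h, w = img.shape
    a = np.deg2rad(angle_deg)
    # direction in (row, col): row axis points down
    dr, dc = -np.sin(a), np.cos(a)
    r_mid, c_mid = center
    half = length / 2.0
    p0 = np.array([r_mid - half * dr, c_mid - half * dc])
    p1 = np.array([r_mid + half * dr, c_mid + half * dc])
    pad = thickness / 2.0 + 1.0
    r_lo = max(0, int(np.floor(min(p0[0], p1[0]) - pad)))
    r_hi = min(h, int(np.ceil(max(p0[0], p1[0]) + pad)) + 1)
    c_lo = max(0, int(np.floor(min(p0[1], p1[1]) - pad)))
    c_hi = min(w, int(np.ceil(max(p0[1], p1[1]) + pad)) + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return (r_lo, r_lo, c_lo, c_lo)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        t = np.zeros_like(rr)
    else:
        t = np.clip(((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / vv, 0.0, 1.0)
    dist = np.hypot(rr - (p0[0] + t * v[0]), cc - (p0[1] + t * v[1]))
    mask = dist <= thickness / 2.0
    region = img[r_lo:r_hi, c_lo:c_hi]
    region[mask] = np.maximum(region[mask], value)
    return (r_lo, r_hi, c_lo, c_hi)


def draw_motif(img: np.ndarray, center, scale: float, thickness: float,
               value: float) -> tuple:
    """Stamp the stick-face motif; returns its bounding box (r0, r1, c0, c1)."""
    r, c = center
    boxes = [
        # eyes: vertical bars (along the row axis)
        draw_bar(img, (r - 0.18 * scale, c - 0.22 * scale), 0.40 * scale, 90.0,
                 thickness, value),
        draw_bar(img, (r - 0.18 * scale, c + 0.22 * scale), 0.40 * scale, 90.0,
                 thickness, value),
        # nose: diagonal bar
        draw_bar(img, (r + 0.02 * scale, c), 0.30 * scale, 45.0, thickness,
                 value),
        # mouth: horizontal bar
        draw_bar(img, (r + 0.30 * scale, c), 0.70 * scale, 0.0, thickness,
                 value),
    ]
    r0 = min(b[0] for b in boxes)
    r1 = max(b[1] for b in boxes)
    c0 = min(b[2] for b in boxes)
    c1 = max(b[3] for b in boxes)
    return (r0, r1, c0, c1)


def _add_clutter(img: np.ndarray, spec: FixtureSpec, rng) -> None:
    count = int(rng.integers(spec.n_clutter[0], spec.n_clutter[1] + 1))
    h, w = img.shape
    for _ in range(count):
        r = float(rng.uniform(0, h))
        c = float(rng.uniform(0, w))
        angle = float(rng.uniform(0.0, 180.0))
        length = float(rng.uniform(*spec.clutter_length))
        value = float(rng.uniform(*spec.bar_value))
        draw_bar(img, (r, c), length, angle, spec.bar_thickness, value)


def generate_dataset(spec: FixtureSpec):
    """Generate the two-class dataset, reproducibly from ``spec.seed``.

    Returns ``(dataset, boxes)`` where ``boxes[image_id]`` is the motif
    bounding box (r0, r1, c0, c1) for positives and ``None`` for negatives.
    """
    if spec.n_pos < 1 or spec.n_neg < 1:
        raise ValueError("need at least one image per class")
    max_scale = spec.motif_scale * (1.0 + spec.scale_jitter)
    half = 0.5 * max_scale + spec.bar_thickness
    r_lo, r_hi = spec.margin + half, spec.height - spec.margin - half
    c_lo, c_hi = spec.margin + half, spec.width - spec.margin - half
    if r_lo >= r_hi or c_lo >= c_hi:
        raise ValueError("motif (plus margin) does not fit inside the image")

    rng = np.random.default_rng(spec.seed)
    images, labels, ids = [], [], []
    boxes = {}
    for i in range(spec.n_pos):
        img = np.zeros((spec.height, spec.width))
        _add_clutter(img, spec, rng)
        scale = spec.motif_scale * (1.0 + rng.uniform(-spec.scale_jitter,
                                                      spec.scale_jitter))
        center = (float(rng.uniform(r_lo, r_hi)), float(rng.uniform(c_lo, c_hi)))
        value = float(rng.uniform(*spec.bar_value))
        box = draw_motif(img, center, scale, spec.bar_thickness, value)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, img.shape)
        img_id = f"pos_{i:03d}"
        images.append(np.clip(img, 0.0, 1.0))
        labels.append(1)
        ids.append(img_id)
        boxes[img_id] = box
    for i in range(spec.n_neg):
        img = np.zeros((spec.height, spec.width))
        _add_clutter(img, spec, rng)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, img.shape)
        img_id = f"neg_{i:03d}"
        images.append(np.clip(img, 0.0, 1.0))
        labels.append(-1)
        ids.append(img_id)
        boxes[img_id] = None
    ds = LabeledDataset(images=images, labels=np.asarray(labels), ids=ids)
    return ds, boxes


def c1_cell_rect(i: int, j: int, band: int, cfg: C1Config | None = None) -> tuple:
    """Image-space rectangle of C1 cell (i, j) of a band (end-exclusive).

    Cell (i, j) pools the pixels ``[i * stride, i * stride + N^Sigma) x
    [j * stride, j * stride + N^Sigma)`` of the input image.
    """
    cfg = cfg if cfg is not None else default_c1_config()
    stride, n = cfg.stride(band), cfg.grid_size[band]
    return (i * stride, i * stride + n, j * stride, j * stride + n)


def patch_footprint(patch: Patch, cfg: C1Config | None = None) -> tuple:
    """Image-space rectangle covered by a patch's C1 cells (end-exclusive)."""
    cfg = cfg if cfg is not None else default_c1_config()
    r, c = patch.position
    n = patch.size_n
    r0, _, c0, _ = c1_cell_rect(r, c, patch.band, cfg)
    _, r1, _, c1_ = c1_cell_rect(r + n - 1, c + n - 1, patch.band, cfg)
    return (r0, r1, c0, c1_)


def patch_on_motif(patch: Patch, boxes: dict,
                   cfg: C1Config | None = None) -> bool:
    """True iff the patch's image-space footprint overlaps its source image's
    motif box by at least 50% of the patch footprint area.

    Patches from negative images (box ``None``) are never on-motif; an
    unknown source image raises.
    """
    if patch.source_image not in boxes:
        raise ValueError(f"unknown source image: {patch.source_image}")
    box = boxes[patch.source_image]
    if box is None:
        return False
    fr0, fr1, fc0, fc1 = patch_footprint(patch, cfg)
    area = (fr1 - fr0) * (fc1 - fc0)
    br0, br1, bc0, bc1 = box
    inter = max(0, min(fr1, br1) - max(fr0, br0)) * \
        max(0, min(fc1, bc1) - max(fc0, bc0))
    return inter >= 0.5 * area
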