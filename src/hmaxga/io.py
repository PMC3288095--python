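"""Image loading, geometric preprocessing and feature-matrix serialization.

Images are held as 2-D float arrays with intensities in [0, 1] (row-major,
0-based).  Datasets are plain directories with one sub-directory per class::

    <root>/<class_name>/*.png

and an explicit ``{class_name: +1 | -1}`` mapping (+1 = target,
-1 = background).  Feature matrices (patches x images) round-trip through
human-inspectable CSV at better than 12 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass
class LabeledDataset:
    """Ordered two-class image collection.

    Attributes
    ----------
    images
        List of 2-D float arrays in [0, 1].
    labels
        Array of +1 (target) / -1 (background), aligned with ``images``.
    ids
        Stable, unique string identifiers, aligned with ``images``.
    """

    images: list
    labels: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.ids = list(self.ids)
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValueError("images, labels and ids must have equal length")
        extra = set(np.unique(self.labels)) - {1, -1}
        if extra:
            raise ValueError(f"labels must be +1 or -1, got {sorted(extra)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("image ids must be unique")
        self._index = {img_id: k for k, img_id in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.images)

    def index_of(self, image_id: str) -> int:
        try:
            return self._index[image_id]
        except KeyError:
            raise KeyError(f"unknown image id: {image_id}") from None

    def label_of(self, image_id: str) -> int:
        return int(self.labels[self.index_of(image_id)])

    def image_of(self, image_id: str) -> np.ndarray:
        return self.images[self.index_of(image_id)]

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        idx = [self.index_of(i) for i in ids]
        return LabeledDataset(
            images=[self.images[k] for k in idx],
            labels=self.labels[idx],
            ids=[self.ids[k] for k in idx],
        )


def load_image(path) -> np.ndarray:
    """Decode a raster image to grayscale intensities in [0, 1].

    Color inputs are converted to luminance with Rec. 601 weights
    (0.299 R + 0.587 G + 0.114 B); 8-bit values are scaled by 1/255.

    Raises
    ------
    OSError
        If the file is missing or not a decodable raster image.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise OSError(f"image file {path} did not decode to a 2-D image")
    return arr


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] grayscale array as an 8-bit image file."""
    img = np.asarray(img, dtype=float)
    _validate_gray(img)
    data = np.clip(np.floor(img * 255.0 + 0.5), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path))


def _validate_gray(img: np.ndarray) -> None:
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected a non-empty 2-D grayscale array")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")


def preprocess(img: np.ndarray, target_height: int = 140) -> np.ndarray:
    """Resize to a fixed height, width scaled proportionally.

    Bilinear interpolation; the output width is
    ``round(width * target_height / height)`` (half-away-from-zero, floor 1 px).
    An image already at the target height is returned unchanged (copy).
    """
    img = np.asarray(img, dtype=float)
    _validate_gray(img)
    if target_height < 1:
        raise ValueError("target_height must be >= 1")
    h, w = img.shape
    if h == target_height:
        return img.copy()
    tw = max(1, int(np.floor(w * target_height / h + 0.5)))
    out = resize(
        img,
        (target_height, tw),
        order=1,
        mode="reflect",
        anti_aliasing=target_height < h,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def load_dataset(
    root,
    class_labels: Mapping[str, int],
    target_height: int | None = None,
) -> LabeledDataset:
    """Load a ``<root>/<class>/*`` directory tree as a labeled dataset.

    Parameters
    ----------
    class_labels
        Maps sub-directory name to label (+1 or -1).
    target_height
        If given, every image is resized with :func:`preprocess`.
    """
    root = Path(root)
    images, labels, ids = [], [], []
    for cls in sorted(class_labels):
        label = int(class_labels[cls])
        cls_dir = root / cls
        if not cls_dir.is_dir():
            raise OSError(f"class directory not found: {cls_dir}")
        files = sorted(
            p for p in cls_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        )
        if not files:
            raise OSError(f"no images found under {cls_dir}")
        for path in files:
            img = load_image(path)
            if target_height is not None:
                img = preprocess(img, target_height)
            images.append(img)
            labels.append(label)
            ids.append(f"{cls}/{path.stem}")
    return LabeledDataset(images=images, labels=np.asarray(labels), ids=ids)


def write_feature_matrix(matrix, path) -> None:
    """Serialize a feature matrix (patches x images) as CSV.

    First column holds patch ids, the header row holds image ids.  Values are
    written with 17 significant digits so a round trip preserves at least 12.

    Raises
    ------
    ValueError
        On an empty matrix or non-finite entries.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
        raise ValueError("feature matrix must be 2-D and non-empty")
    if not np.isfinite(values).all():
        raise ValueError("feature matrix contains non-finite values")
    df = pd.DataFrame(values, index=list(matrix.patch_ids),
                      columns=list(matrix.image_ids))
    df.to_csv(path, float_format="%.17g", index_label="patch_id")


def read_feature_matrix(path):
    """Inverse of :func:`write_feature_matrix`.

    Raises
    ------
    ValueError
        On a malformed file, naming the offending line where possible.
    """
    from .s2c2 import C2Matrix  # local import: io must stay s2c2-agnostic

    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature matrix {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"malformed feature matrix {path}: empty table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric_line(df)
        raise ValueError(
            f"malformed feature matrix {path}: non-numeric value at line {bad}"
        ) from exc
    return C2Matrix(values=values, patch_ids=[str(i) for i in df.index],
                    image_ids=[str(c) for c in df.columns])


def _first_non_numeric_line(df: pd.DataFrame) -> int:
    for row_pos in range(df.shape[0]):
        try:
            df.iloc[row_pos].astype(float)
        except (TypeError, ValueError):
            return row_pos + 2  # +1 header line, +1 one-based
    return -1
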