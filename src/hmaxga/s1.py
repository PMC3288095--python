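"""The S1 stage: a pyramid of Gabor filters modeling V1 simple cells.

Each filter is the product of a sinusoidal carrier and a Gaussian envelope on
rotated coordinates::

    x0 =  x cos(theta) + y sin(theta)
    y0 = -x sin(theta) + y cos(theta)
    k(x, y) = exp(-(x0^2 + gamma^2 y0^2) / (2 sigma^2)) * cos(2 pi x0 / lambda)

restricted to a circular aperture of radius size/2, then mean-subtracted and
scaled to unit Euclidean norm.  The default bank has 16 sizes (7..37 step 2)
times 4 orientations = 64 filters; adjacent size pairs form 8 scale bands.

Applying the bank yields, per filter, the absolute value of the correlation
with each local neighborhood divided by the neighborhood's Euclidean norm over
the filter's aperture, so responses lie in [0, 1] (Cauchy-Schwarz).  Outputs
keep the input's spatial dimensions; borders are handled by symmetric
(edge-reflecting) padding, with the norm divisor computed over the padded
window.  Reflective padding keeps border windows of a constant image
constant, so zero-mean kernels annihilate constants everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import fftconvolve

from .config import default_config

_DENOM_EPS = 1e-12


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single Gabor filter.

    size: odd kernel side in px; theta: orientation in degrees;
    sigma: Gaussian envelope width in px; gamma: aspect ratio;
    lam: carrier wavelength in px.
    """

    size: int
    theta: float
    sigma: float
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 3, got {self.size}")
        if self.sigma <= 0 or self.lam <= 0 or self.gamma <= 0:
            raise ValueError("sigma, lam and gamma must be positive")
        if not 0 <= self.theta < 180:
            raise ValueError("theta must lie in [0, 180) degrees")


def make_gabor_kernel(p: GaborParams) -> np.ndarray:
    """Build one zero-mean, unit-norm Gabor kernel on a circular aperture."""
    half = p.size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    th = np.deg2rad(p.theta)
    x0 = x * np.cos(th) + y * np.sin(th)
    y0 = -x * np.sin(th) + y * np.cos(th)
    k = np.exp(-(x0**2 + (p.gamma * y0) ** 2) / (2.0 * p.sigma**2))
    k *= np.cos(2.0 * np.pi * x0 / p.lam)
    inside = (x**2 + y**2) <= (p.size / 2.0) ** 2
    k[~inside] = 0.0
    k[inside] -= k[inside].mean()
    norm = float(np.linalg.norm(k))
    if norm < _DENOM_EPS:
        raise ValueError("degenerate Gabor kernel: zero after mean removal")
    return k / norm


def aperture_mask(size: int) -> np.ndarray:
    """Binary circular aperture of radius size/2 (float array)."""
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    return ((x**2 + y**2) <= (size / 2.0) ** 2).astype(float)


@dataclass
class FilterBank:
    """Ordered Gabor pyramid: size-major, orientation-minor.

    ``band_index`` maps band number (1-based) to the two adjacent filter
    sizes it pools.
    """

    params: list
    kernels: list
    sizes: tuple
    thetas: tuple
    band_index: dict

    def __post_init__(self) -> None:
        self._lookup = {
            (p.size, p.theta): k for p, k in zip(self.params, self.kernels)
        }

    def kernel(self, size: int, theta: float) -> np.ndarray:
        return self._lookup[(size, float(theta))]

    @property
    def n_bands(self) -> int:
        return len(self.band_index)

    @property
    def max_size(self) -> int:
        return max(self.sizes)


def build_filter_bank(cfg: Mapping | None = None) -> FilterBank:
    """Build the filter pyramid from a configuration dict.

    ``cfg`` follows the layout of :func:`hmaxga.config.default_config`
    (the ``"s1"`` section is used).  Raises a config error naming any size
    that lacks (sigma, lambda) values.
    """
    cfg = cfg if cfg is not None else default_config()
    s1 = cfg["s1"]
    sizes = tuple(sorted(int(s) for s in s1["sizes"]))
    thetas = tuple(float(t) for t in s1["orientations"])
    gamma = float(s1["gamma"])
    if len(sizes) % 2 != 0:
        raise ValueError("the size list must pair into bands (even count)")
    params, kernels = [], []
    for size in sizes:
        if size not in s1["sigma"] or size not in s1["lam"]:
            raise ValueError(f"config missing Gabor parameters for size {size}")
        for theta in thetas:
            p = GaborParams(size=size, theta=theta, sigma=float(s1["sigma"][size]),
                            gamma=gamma, lam=float(s1["lam"][size]))
            params.append(p)
            kernels.append(make_gabor_kernel(p))
    band_index = {
        b: (sizes[2 * (b - 1)], sizes[2 * b - 1])
        for b in range(1, len(sizes) // 2 + 1)
    }
    return FilterBank(params=params, kernels=kernels, sizes=sizes,
                      thetas=thetas, band_index=band_index)


@dataclass
class S1Maps:
    """Stack of filter responses, indexed ``responses[size_idx, theta_idx]``."""

    responses: np.ndarray  # (n_sizes, n_thetas, H, W)
    sizes: tuple
    thetas: tuple

    @property
    def shape(self) -> tuple:
        return self.responses.shape[2:]

    def map(self, size: int, theta: float) -> np.ndarray:
        return self.responses[self.sizes.index(size), self.thetas.index(float(theta))]


def apply_s1(img: np.ndarray, bank: FilterBank, normalize: bool = True) -> S1Maps:
    """Filter an image with the whole bank.

    Returns same-size response maps (symmetric border padding).  With
    ``normalize`` the response at each pixel is |k . v| / ||v|| with v the
    neighborhood over the kernel's circular aperture (zero where the
    neighborhood norm vanishes); without it, the raw |k . v|.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(img.shape) < bank.max_size:
        raise ValueError(
            f"image {img.shape} smaller than the largest kernel "
            f"({bank.max_size}x{bank.max_size})"
        )
    n_sizes, n_thetas = len(bank.sizes), len(bank.thetas)
    out = np.empty((n_sizes, n_thetas) + img.shape, dtype=float)
    for si, size in enumerate(bank.sizes):
        half = size // 2
        padded = np.pad(img, half, mode="symmetric")
        if normalize:
            mask = aperture_mask(size)
            denom = fftconvolve(padded * padded, mask, mode="valid")
            denom = np.sqrt(np.clip(denom, 0.0, None))
            ok = denom > _DENOM_EPS
        for ti, theta in enumerate(bank.thetas):
            k = bank.kernel(size, theta)
            num = np.abs(fftconvolve(padded, k[::-1, ::-1], mode="valid"))
            if normalize:
                resp = np.zeros_like(num)
                np.divide(num, denom, out=resp, where=ok)
                out[si, ti] = np.clip(resp, 0.0, 1.0)
            else:
                out[si, ti] = num
    return S1Maps(responses=out, sizes=bank.sizes, thetas=bank.thetas)
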