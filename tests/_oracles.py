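"""Independent brute-force oracles used by the tests.

These implement the same quantities as the package by direct enumeration
(explicit loops, closed forms) and deliberately share no code with the
implementation they check.
"""

from __future__ import annotations

import numpy as np


def gabor_closed_form(size, theta, sigma, gamma, lam):
    """Direct per-element evaluation of the Gabor closed form, including the
    circular aperture, mean subtraction and norm normalization."""
    half = size // 2
    th = np.deg2rad(theta)
    raw = np.zeros((size, size))
    inside = np.zeros((size, size), dtype=bool)
    for i in range(size):
        for j in range(size):
            y, x = i - half, j - half
            if x * x + y * y > (size / 2.0) ** 2:
                continue
            x0 = x * np.cos(th) + y * np.sin(th)
            y0 = -x * np.sin(th) + y * np.cos(th)
            raw[i, j] = np.exp(-(x0**2 + (gamma * y0) ** 2)
                               / (2.0 * sigma**2)) * np.cos(2 * np.pi * x0 / lam)
            inside[i, j] = True
    raw[inside] -= raw[inside].mean()
    return raw / np.linalg.norm(raw)


def s1_sliding_window(img, kernel, size):
    """Per-pixel |k . v| / ||v|| with symmetric border padding, v restricted
    to the kernel's circular aperture; explicit double loop."""
    half = size // 2
    padded = np.pad(img, half, mode="symmetric")
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    aperture = (xx**2 + yy**2) <= (size / 2.0) ** 2
    out = np.zeros_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            window = padded[r:r + size, c:c + size]
            num = abs(float((kernel * window).sum()))
            den = float(np.sqrt((window[aperture] ** 2).sum()))
            out[r, c] = 0.0 if den <= 1e-12 else min(num / den, 1.0)
    return out


def max_pool_windows(m, n, overlap):
    """Exhaustive clipped-window max pooling."""
    import math

    stride = n - overlap
    h, w = m.shape
    oh = math.ceil((h - n) / stride) + 1
    ow = math.ceil((w - n) / stride) + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            vals = []
            for r in range(i * stride, min(i * stride + n, h)):
                for c in range(j * stride, min(j * stride + n, w)):
                    vals.append(m[r, c])
            out[i, j] = max(vals)
    return out


def s2_distance_map(band_arr, patch_values):
    """Explicit-loop Euclidean distances of a patch against every block of a
    (4, h, w) band map; returns the distance grid."""
    n = patch_values.shape[1]
    _, h, w = band_arr.shape
    out = np.zeros((h - n + 1, w - n + 1))
    for r in range(h - n + 1):
        for c in range(w - n + 1):
            d2 = 0.0
            for o in range(band_arr.shape[0]):
                for i in range(n):
                    for j in range(n):
                        diff = band_arr[o, r + i, c + j] - patch_values[o, i, j]
                        d2 += diff * diff
            out[r, c] = np.sqrt(d2)
    return out


def eer_sweep(scores, labels):
    """Equal-error rate by exhaustive threshold sweep with linear
    interpolation between adjacent operating points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = ~pos
    pts = [(0.0, 1.0)]  # threshold above every score: fpr 0, fnr 1
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        pts.append((float(pred[neg].mean()), float((~pred[pos]).mean())))
    prev_fpr, prev_fnr = pts[0]
    for fpr, fnr in pts[1:]:
        d_prev, d_cur = prev_fpr - prev_fnr, fpr - fnr
        if d_cur >= 0:
            if d_cur == 0:
                return fpr
            t = -d_prev / (d_cur - d_prev)
            return prev_fpr + t * (fpr - prev_fpr)
        prev_fpr, prev_fnr = fpr, fnr
    raise AssertionError("no equal-error crossing found")


def auc_all_pairs(scores, labels):
    """AUC as the all-pairs rank statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_best_subset(n_bits, fitness_fn):
    """Minimum fitness over all non-empty bit vectors of length n_bits."""
    best_f, best_bits = np.inf, None
    for mask in range(1, 2**n_bits):
        bits = np.array([(mask >> i) & 1 for i in range(n_bits)],
                        dtype=np.uint8)
        f = fitness_fn(bits)
        if f < best_f:
            best_f, best_bits = f, bits
    return best_f, best_bits
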