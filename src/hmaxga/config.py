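"""Default parameterization of the feature hierarchy.

The Gabor pyramid uses 16 filter sizes (7x7 to 37x37 in steps of 2) at four
orientations (0, 45, 90, 135 degrees).  Per-size Gaussian envelope widths
(``sigma``) and carrier wavelengths (``lam``) follow the standard published
HMAX parameterization; all of them can be overridden from a YAML file, e.g.::

    s1:
      gamma: 0.3
      sigma: {7: 2.8, 9: 3.6}
    c1:
      overlap: {1: 4}

Only the keys present in the file are replaced; everything else keeps its
default value.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

GABOR_SIZES = tuple(range(7, 39, 2))

GABOR_SIGMA = {
    7: 2.8, 9: 3.6, 11: 4.5, 13: 5.4, 15: 6.3, 17: 7.3, 19: 8.2, 21: 9.2,
    23: 10.2, 25: 11.3, 27: 12.3, 29: 13.4, 31: 14.6, 33: 15.8, 35: 17.0,
    37: 18.2,
}

GABOR_LAMBDA = {
    7: 3.5, 9: 4.6, 11: 5.6, 13: 6.8, 15: 7.9, 17: 9.1, 19: 10.3, 21: 11.5,
    23: 12.7, 25: 14.1, 27: 15.4, 29: 16.8, 31: 18.2, 33: 19.7, 35: 21.2,
    37: 22.8,
}

ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)

GABOR_GAMMA = 0.3

N_BANDS = 8


def default_config() -> dict:
    """Full default configuration as a plain nested dict."""
    grid = {b: 8 + 2 * (b - 1) for b in range(1, N_BANDS + 1)}
    return {
        "s1": {
            "sizes": list(GABOR_SIZES),
            "orientations": list(ORIENTATIONS),
            "gamma": GABOR_GAMMA,
            "sigma": dict(GABOR_SIGMA),
            "lam": dict(GABOR_LAMBDA),
        },
        "c1": {
            "grid_size": grid,
            # half-overlap pooling grid: stride = N - Delta_s = N / 2
            "overlap": {b: n // 2 for b, n in grid.items()},
        },
        "s2": {"tuning_sigma": 1.0, "mode": "gaussian"},
    }


def _deep_update(base: dict, other: dict) -> dict:
    for key, value in other.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file.

    Parameters
    ----------
    path
        YAML file with any subset of the keys of :func:`default_config`.
    """
    cfg = copy.deepcopy(default_config())
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, user)
    return cfg
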