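"""Shared thresholding helper for sparse-foreground volumes."""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu


def sparse_otsu_threshold(v: np.ndarray, max_foreground_fraction: float = 0.2) -> float:
    """Otsu threshold that is robust to a dominant background mode.

    When foreground occupies far less than half the volume, plain Otsu
    splits the background instead of separating signal. The threshold is
    recomputed on the above-threshold subset until the foreground fraction
    is at most ``max_foreground_fraction`` (deterministic; a handful of
    iterations at most).
    """
    v = np.asarray(v, dtype=float)
    if v.max() == v.min():
        raise ValueError("cannot threshold a constant volume")
    thr = threshold_otsu(v)
    for _ in range(16):
        fg = v > thr
        if fg.mean() <= max_foreground_fraction:
            break
        sub = v[fg]
        if np.unique(sub).size < 2:
            break
        new_thr = threshold_otsu(sub)
        if new_thr <= thr:
            break
        thr = new_thr
    return float(thr)
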