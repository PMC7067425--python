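"""Independent brute-force oracles shared by the test modules.

These deliberately use naive per-pixel / per-element loops so they share no
code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def dice_oracle(
    pred: np.ndarray, truth: np.ndarray, n_classes: int, absent: str = "one"
) -> tuple[float, float]:
    """Micro/macro Dice from an explicitly tallied confusion matrix."""
    tp = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p == t:
            tp[p] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    micro = 2 * sum(tp) / (2 * sum(tp) + sum(fp) + sum(fn))
    per_class = []
    for c in range(n_classes):
        denom = 2 * tp[c] + fp[c] + fn[c]
        if denom == 0:
            if absent == "one":
                per_class.append(1.0)
        else:
            per_class.append(2 * tp[c] / denom)
    macro = float(np.mean(per_class))
    return float(micro), macro


def grid_mask_oracle(height: int, width: int, patch: int, half_width: int) -> np.ndarray:
    """Edge-vicinity mask by looping over every pixel and every grid line."""
    lines = list(range(patch, max(height, width), patch))
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            for line in lines:
                if line < height:
                    d = r - line if r >= line else line - 1 - r
                    if d < half_width:
                        mask[r, c] = True
                if line < width:
                    d = c - line if c >= line else line - 1 - c
                    if d < half_width:
                        mask[r, c] = True
    return mask


def count_origins_oracle(extent: int, patch: int, stride: int) -> int:
    """Count tile origins along one axis by explicit enumeration."""
    count = 0
    pos = 0
    while pos + patch <= extent:
        count += 1
        pos += stride
    return count
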