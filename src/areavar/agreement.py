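"""Agreement between relative-risk estimates from alternative models."""

from __future__ import annotations

import warnings

import numpy as np


def icc_agreement(rr_a: np.ndarray, rr_b: np.ndarray) -> float:
    """One-way random-effects intraclass correlation, ICC(1,1).

    Treats the two per-cell estimates as paired ratings of each (area, year)
    cell: with between-cell mean square MSB and within-cell mean square MSW
    from the one-way ANOVA, ``ICC = (MSB - MSW) / (MSB + MSW)`` for two
    raters.  Ranges in [-1/(n-1), 1]; NaN (with a warning) when both vectors
    are constant.
    """
    a = np.asarray(rr_a, dtype=float).reshape(-1)
    b = np.asarray(rr_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("estimates must align cell-by-cell")
    n = a.size
    if n < 3:
        raise ValueError("ICC needs at least 3 cells")
    x = np.column_stack([a, b])  # (n, k=2)
    k = 2
    cell_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((cell_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - cell_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        warnings.warn("zero variance in both estimate vectors; ICC undefined",
                      stacklevel=2)
        return float("nan")
    return float((msb - msw) / denom)
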