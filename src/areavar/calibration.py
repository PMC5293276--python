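"""Predictive calibration via the probability integral transform.

For count data the PIT is degenerate, so the non-randomized mean-PIT
adjustment is used: with posterior-predictive CDF ``F`` averaged over draws,
each cell contributes ``u = (F(o - 1) + F(o)) / 2``.  A calibrated model
yields approximately uniform ``u``; a U-shaped histogram signals
underdispersion of the predictive (overdispersed data), a hump-shaped one
overdispersion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import poisson

from .model import PosteriorSummary
from .panel import CountsPanel


@dataclasses.dataclass(frozen=True)
class PitResult:
    """PIT histogram with a chi-square uniformity statistic."""

    pit: np.ndarray        # one value per (area, year) cell with exposure
    hist: np.ndarray       # (bins,)
    bin_edges: np.ndarray  # (bins + 1,)
    statistic: float       # sum_b (n_b - n/B)^2 / (n/B)
    n_cells: int

    def is_u_shaped(self) -> bool:
        """Whether the extreme bins dominate the middle ones."""
        ends = min(self.hist[0], self.hist[-1])
        middle = self.hist[1:-1]
        return bool(ends > middle.mean())


def pit_calibration(
    panel: CountsPanel,
    summary: PosteriorSummary,
    *,
    bins: int = 10,
    max_draws: int = 400,
    leave_one_out: bool = True,
) -> PitResult:
    """Mean-PIT histogram of the fitted model on its own panel.

    By default the predictive CDF for each cell is the importance-weighted
    leave-one-out predictive (draw weights proportional to the reciprocal of
    that cell's likelihood), the standard correction for the central hump
    that in-sample posterior predictives produce by conditioning on the very
    observation being checked; ``leave_one_out=False`` gives the plain
    posterior-averaged predictive.  Uses at most ``max_draws`` evenly spaced
    posterior draws.  Cells with zero expected counts are excluded.
    """
    eta = summary.linear_predictor_draws()  # (D, I, T)
    D = eta.shape[0]
    if D > max_draws:
        eta = eta[np.linspace(0, D - 1, max_draws).astype(int)]
    mu = panel.e[None, :, :] * np.exp(eta)
    live = panel.e > 0
    o = panel.o[None, :, :]
    F_o = poisson.cdf(o, mu)
    F_om1 = poisson.cdf(o - 1, mu)
    if leave_one_out:
        logw = -poisson.logpmf(o, mu)
        logw -= logw.max(axis=0, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=0, keepdims=True)
        F_o = (w * F_o).sum(axis=0)
        F_om1 = (w * F_om1).sum(axis=0)
    else:
        F_o = F_o.mean(axis=0)
        F_om1 = F_om1.mean(axis=0)
    u = 0.5 * (F_o + F_om1)
    u = u[live]
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(u, bins=edges)
    n = u.size
    expected = n / bins
    stat = float(np.sum((hist - expected) ** 2 / expected))
    return PitResult(
        pit=u, hist=hist, bin_edges=edges, statistic=stat, n_cells=n
    )
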