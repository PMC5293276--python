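"""Variance partitioning of the fitted log-risk surface.

The four latent components live on different index sets (areas, regions,
years, region x year).  To make them commensurable each is expanded to the
common (area, year) grid; the fraction of variance of a component is its
empirical grid variance divided by the total, computed per posterior draw
and averaged.  A per-unit weighting (variance over each component's native
index set) is available since the cell/unit choice is a genuine analysis
decision.  The module also provides the yearly risk-variance series, the
exclude-and-refit sensitivity analysis, and an advisory flagger for regions
whose interaction trajectory departs from the common trend.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .geography import Geography
from .model import ModelSpec, PosteriorSummary, fit
from .panel import CountsPanel, ModelComponents

COMPONENT_NAMES = ("HA", "AC", "temporal", "interaction")


@dataclasses.dataclass(frozen=True)
class VarianceDecomposition:
    """Per-component variances and fractions of the log-risk surface."""

    variances: dict[str, float]   # component -> variance (log-risk scale)
    fractions: dict[str, float]   # component -> fraction in [0, 1]
    weighting: str                # "cell" | "unit"
    source: str                   # "posterior" | "generative"

    def __post_init__(self) -> None:
        tot = sum(self.fractions.values())
        if abs(tot - 1.0) > 1e-10:
            raise ValueError(f"fractions must sum to 1, got {tot}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(COMPONENT_NAMES),
                "variance": [self.variances[c] for c in COMPONENT_NAMES],
                "fraction": [self.fractions[c] for c in COMPONENT_NAMES],
                "weighting": self.weighting,
                "source": self.source,
            }
        )


def expand_to_grid(
    u: np.ndarray,
    v: np.ndarray,
    gamma: np.ndarray,
    delta: np.ndarray,
    geo: Geography,
    T: int,
) -> dict[str, np.ndarray]:
    """Broadcast each component to the (area, year) grid.

    The sum of the four surfaces plus the intercept reconstructs the linear
    predictor cell-by-cell.
    """
    ri = geo.region_index
    I = geo.n_areas
    return {
        "HA": np.broadcast_to(u[:, None], (I, T)).copy(),
        "AC": np.broadcast_to(v[ri][:, None], (I, T)).copy(),
        "temporal": np.broadcast_to(gamma[None, :], (I, T)).copy(),
        "interaction": delta[ri, :].copy(),
    }


def _component_variances(
    u, v, gamma, delta, geo: Geography, T: int, weighting: str
) -> dict[str, float]:
    if weighting == "cell":
        surf = expand_to_grid(u, v, gamma, delta, geo, T)
        return {k: float(np.var(s)) for k, s in surf.items()}
    if weighting == "unit":
        return {
            "HA": float(np.var(u)),
            "AC": float(np.var(v)),
            "temporal": float(np.var(gamma)),
            "interaction": float(np.var(delta)),
        }
    raise ValueError(f"unknown weighting {weighting!r}")


def _normalize(variances: dict[str, float], weighting: str, source: str
               ) -> VarianceDecomposition:
    total = sum(variances.values())
    if total <= 0:
        raise ValueError("total variance is zero; fractions undefined")
    fr = {k: v / total for k, v in variances.items()}
    # exact renormalization so fractions sum to one to machine precision
    s = sum(fr.values())
    fr = {k: v / s for k, v in fr.items()}
    return VarianceDecomposition(variances, fr, weighting, source)


def fractions_from_components(
    comps: ModelComponents, geo: Geography, *, weighting: str = "cell"
) -> VarianceDecomposition:
    """Generative (true-surface) variance decomposition of drawn components."""
    T = comps.gamma.size
    var = _component_variances(
        comps.u, comps.v, comps.gamma, comps.delta, geo, T, weighting
    )
    return _normalize(var, weighting, "generative")


def fractions_of_variance(
    summary: PosteriorSummary, *, weighting: str = "cell"
) -> VarianceDecomposition:
    """Posterior variance decomposition: per-draw grid variances, averaged.

    Absent components (switched off in the model spec) contribute zero
    variance.
    """
    geo, T = summary.geo, len(summary.years)
    I, J = geo.n_areas, geo.n_regions
    D = summary.n_draws
    zeros = {
        "u": np.zeros((D, I)),
        "v": np.zeros((D, J)),
        "gamma": np.zeros((D, T)),
        "delta": np.zeros((D, J, T)),
    }
    draws = {
        k: (summary.component_draws(k)
            if getattr(summary, k) is not None else zeros[k])
        for k in ("u", "v", "gamma", "delta")
    }
    acc = {k: 0.0 for k in COMPONENT_NAMES}
    for d in range(D):
        var = _component_variances(
            draws["u"][d], draws["v"][d], draws["gamma"][d], draws["delta"][d],
            geo, T, weighting,
        )
        for k in acc:
            acc[k] += var[k]
    var = {k: acc[k] / D for k in acc}
    return _normalize(var, weighting, "posterior")


def yearly_risk_variance(
    summary: PosteriorSummary, *, basis: str = "log_rr"
) -> pd.Series:
    """Variance across areas of the posterior-mean (log) relative risk.

    One value per year; ``basis`` chooses the log-risk (default) or risk
    scale and is recorded in the series name.
    """
    if basis == "log_rr":
        surface = summary.linear_predictor_draws().mean(axis=0)
    elif basis == "rr":
        surface = summary.rr_mean
    else:
        raise ValueError(f"unknown basis {basis!r}")
    values = surface.var(axis=0)
    return pd.Series(values, index=list(summary.years),
                     name=f"yearly_variance[{basis}]")


@dataclasses.dataclass(frozen=True)
class SensitivityResult:
    """Side-by-side decomposition with and without the excluded regions."""

    full: VarianceDecomposition
    reduced: VarianceDecomposition
    excluded_regions: tuple[str, ...]
    summary_full: PosteriorSummary
    summary_reduced: PosteriorSummary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(COMPONENT_NAMES),
                "fraction_full": [self.full.fractions[c] for c in COMPONENT_NAMES],
                "fraction_reduced": [
                    self.reduced.fractions[c] for c in COMPONENT_NAMES
                ],
                "excluded_regions": ",".join(self.excluded_regions),
            }
        )


def sensitivity_refit(
    panel: CountsPanel,
    geo: Geography,
    spec: ModelSpec | None = None,
    exclude_regions: Sequence[str] = (),
    *,
    weighting: str = "cell",
    full_summary: PosteriorSummary | None = None,
    **fit_kwargs,
) -> SensitivityResult:
    """Exclude whole regions, refit, and compare variance decompositions.

    Exclusion is by region — all member areas are dropped — mirroring the
    removal of regions with singular trajectories.  A precomputed full fit
    can be passed to avoid refitting it.
    """
    exclude = tuple(exclude_regions)
    unknown = [r for r in exclude if r not in geo.region_ids]
    if unknown:
        raise ValueError(f"unknown regions to exclude: {unknown}")
    keep = [r for r in geo.region_ids if r not in set(exclude)]
    if len(keep) < 2:
        raise ValueError("exclusion must leave at least 2 regions")
    if full_summary is None:
        full_summary = fit(panel, geo, spec, **fit_kwargs)
    sub_geo = geo.subset(keep)
    keep_pos = np.array(
        [i for i, a in enumerate(geo.area_ids) if a in set(sub_geo.area_ids)]
    )
    sub_panel = panel.subset(keep_pos)
    reduced_summary = fit(sub_panel, sub_geo, spec, **fit_kwargs)
    return SensitivityResult(
        full=fractions_of_variance(full_summary, weighting=weighting),
        reduced=fractions_of_variance(reduced_summary, weighting=weighting),
        excluded_regions=exclude,
        summary_full=full_summary,
        summary_reduced=reduced_summary,
    )


def singular_region_flagger(summary: PosteriorSummary) -> pd.DataFrame:
    """Rank regions by the discrepancy of their interaction trajectory.

    Score per region: mean over years of |posterior mean delta_jt|
    standardized by the posterior SD of delta_jt.  Advisory only — it orders
    candidates for the exclude-and-refit sensitivity analysis.
    """
    if summary.delta is None:
        raise ValueError("model has no interaction component to score")
    d = summary.component_draws("delta")  # (D, J, T)
    post_mean = d.mean(axis=0)
    post_sd = d.std(axis=0)
    post_sd = np.where(post_sd > 0, post_sd, np.inf)
    score = (np.abs(post_mean) / post_sd).mean(axis=1)
    out = pd.DataFrame(
        {"region_id": list(summary.geo.region_ids), "score": score}
    ).sort_values("score", ascending=False, kind="stable")
    return out.reset_index(drop=True)
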