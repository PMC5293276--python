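"""Observed/expected count panels on the area x year grid."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class CountsPanel:
    """Hospitalization counts and expected counts per (area, year).

    ``o`` holds observed counts, ``e`` expected counts under the reference
    rates, ``person_years`` the total population at risk.  When available,
    ``o_strat`` keeps the stratified observed counts (area, year, stratum)
    needed for internal (indirect) standardization.
    """

    area_ids: tuple[str, ...]
    years: tuple[int, ...]
    o: np.ndarray  # (I, T) int
    e: np.ndarray  # (I, T) float
    person_years: np.ndarray  # (I, T) float
    condition_label: str = ""
    o_strat: np.ndarray | None = None  # (I, T, S) int
    strata: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        I, T = len(self.area_ids), len(self.years)
        for name in ("o", "e", "person_years"):
            arr = getattr(self, name)
            if arr.shape != (I, T):
                raise ValueError(f"{name} shape {arr.shape} != {(I, T)}")
        if np.any(self.o < 0):
            raise ValueError("observed counts must be non-negative")
        if np.any(self.e < 0):
            raise ValueError("expected counts must be non-negative")
        bad = (self.e == 0) & (self.person_years > 0) & (self.o > 0)
        if np.any(bad):
            raise ValueError("cells with observed events must have e > 0")
        if self.o_strat is not None:
            if self.strata is None:
                raise ValueError("o_strat requires strata labels")
            if self.o_strat.shape[:2] != (I, T):
                raise ValueError("o_strat does not match the (area, year) grid")
            if not np.array_equal(self.o_strat.sum(axis=2), self.o):
                raise ValueError("o_strat must sum to o over strata")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.area_ids, self.years], names=["area_id", "year"]
        )
        return pd.DataFrame(
            {
                "count": self.o.reshape(-1),
                "expected": self.e.reshape(-1),
                "person_years": self.person_years.reshape(-1),
            },
            index=idx,
        ).reset_index()

    def subset(self, area_positions: np.ndarray) -> "CountsPanel":
        """Panel restricted to the given area positions (order preserved)."""
        return CountsPanel(
            area_ids=tuple(self.area_ids[i] for i in area_positions),
            years=self.years,
            o=self.o[area_positions],
            e=self.e[area_positions],
            person_years=self.person_years[area_positions],
            condition_label=self.condition_label,
            o_strat=None if self.o_strat is None else self.o_strat[area_positions],
            strata=self.strata,
        )


@dataclasses.dataclass(frozen=True)
class ModelComponents:
    """Latent log-risk surface components and their precisions.

    The linear predictor decomposes as
    ``log r_it = beta + u_i(j) + v_j + gamma_t + delta_jt``:
    an overall level, an area effect, a region effect, a common temporal
    effect and a region x year interaction.  Precisions are the realized
    precisions of the drawn vectors (1/sample variance; for the temporal
    effect, of its first differences, matching the RW1 prior's increment
    scale), ``inf`` for a degenerate (constant) component.
    """

    beta: float
    u: np.ndarray  # (I,)
    v: np.ndarray  # (J,)
    gamma: np.ndarray  # (T,)
    delta: np.ndarray  # (J, T)
    tau_u: float
    tau_v: float
    tau_gamma: float
    tau_delta: float

    def __post_init__(self) -> None:
        if self.delta.shape != (len(self.v), len(self.gamma)):
            raise ValueError("delta must have shape (J, T)")
        for name in ("tau_u", "tau_v", "tau_gamma", "tau_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def linear_predictor(self, region_index: np.ndarray) -> np.ndarray:
        """log r_it on the (area, year) grid."""
        return (
            self.beta
            + self.u[:, None]
            + self.v[region_index][:, None]
            + self.gamma[None, :]
            + self.delta[region_index, :]
        )
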