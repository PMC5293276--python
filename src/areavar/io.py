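"""File formats, validation and map-/figure-ready exports.

Tables are UTF-8 comma-separated CSV with "." decimals; geographies are JSON
(region/area ids, parent map, adjacency edge list) plus a GeoJSON
FeatureCollection for the polygons.  Every output file carries a metadata
header (tool version, seed, config hash) so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from . import __version__
from .descriptive import expected_counts
from .geography import Geography
from .model import PosteriorSummary
from .panel import CountsPanel
from .population import StratifiedPopulation


class ValidationError(ValueError):
    """Schema violation(s) in an input dataset; lists every problem found."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid dataset:\n- " + "\n- ".join(self.problems))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Paths and settings of one pipeline run (recorded in output headers)."""

    events_path: str = "events.csv"
    population_path: str = "population.csv"
    geography_path: str = "geography.json"
    area_prior: str = "exchangeable"
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    out_dir: str = "out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _metadata_lines(seed: int | None, config_hash: str | None) -> list[str]:
    parts = [f"areavar={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return ["# " + " ".join(parts)]


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config_hash: str | None = None,
    float_format: str = "%.10g",
) -> None:
    """CSV with a one-line ``#`` metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _metadata_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ----------------------------------------------------------------------
# dataset writers / readers


def write_dataset(
    out_dir: str | Path,
    geo: Geography,
    pop: StratifiedPopulation,
    panel: CountsPanel,
    *,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write geography.json, geometry.geojson, population.csv, events.csv
    (stratified long format) and expected.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash() if config else None
    meta = {
        "areavar": __version__,
        **({"seed": seed} if seed is not None else {}),
        **({"config": chash} if chash else {}),
    }
    paths: dict[str, Path] = {}

    gj = {
        "_metadata": meta,
        "region_ids": list(geo.region_ids),
        "area_ids": list(geo.area_ids),
        "parent": dict(geo.parent),
        "adjacency": [list(p) for p in sorted(geo.adjacency or [])],
    }
    paths["geography"] = out / "geography.json"
    paths["geography"].write_text(json.dumps(gj, indent=1, sort_keys=True))

    if geo.geometry is not None:
        features = [
            {
                "type": "Feature",
                "properties": {"area_id": a, "region_id": geo.parent[a]},
                "geometry": mapping(geo.geometry[a]),
            }
            for a in geo.area_ids
        ]
        fc = {"type": "FeatureCollection", "metadata": meta, "features": features}
        paths["geometry"] = out / "geometry.geojson"
        paths["geometry"].write_text(json.dumps(fc))

    paths["population"] = out / "population.csv"
    write_csv(pop.to_frame(), paths["population"], seed=seed, config_hash=chash)

    if panel.o_strat is not None:
        I, T, S = panel.o_strat.shape
        idx = pd.MultiIndex.from_product(
            [panel.area_ids, panel.years, range(S)],
            names=["area_id", "year", "_s"],
        )
        ev = pd.DataFrame(
            {"count": panel.o_strat.reshape(-1)}, index=idx
        ).reset_index()
        ev["age_band"] = [panel.strata[s][0] for s in ev["_s"]]
        ev["sex"] = [panel.strata[s][1] for s in ev["_s"]]
        ev = ev[["area_id", "year", "age_band", "sex", "count"]]
    else:
        ev = panel.to_frame()[["area_id", "year", "count"]]
    paths["events"] = out / "events.csv"
    write_csv(ev, paths["events"], seed=seed, config_hash=chash)

    exp = panel.to_frame()[["area_id", "year", "expected"]]
    paths["expected"] = out / "expected.csv"
    write_csv(exp, paths["expected"], seed=seed, config_hash=chash)
    return paths


def read_panel(
    events_path: str | Path,
    population_path: str | Path,
    geography_path: str | Path,
) -> tuple[CountsPanel, StratifiedPopulation, Geography]:
    """Read and validate a dataset; raises an itemized :class:`ValidationError`.

    Expected counts are taken from ``expected.csv`` next to the events file
    when present, and recomputed by internal standardization otherwise.
    """
    problems: list[str] = []
    gj = json.loads(Path(geography_path).read_text())
    geo = Geography(
        region_ids=tuple(gj["region_ids"]),
        area_ids=tuple(gj["area_ids"]),
        parent=dict(gj["parent"]),
        adjacency=frozenset(tuple(p) for p in gj.get("adjacency", [])),
    )
    pop_df = read_csv(population_path)
    ev_df = read_csv(events_path)
    if ev_df.empty:
        raise ValidationError(["events file contains no rows"])

    areas = set(geo.area_ids)
    for name, df in (("events", ev_df), ("population", pop_df)):
        unknown = sorted(set(df["area_id"]) - areas)
        if unknown:
            problems.append(f"{name} references unknown area_id(s): {unknown}")
    if (ev_df["count"] < 0).any():
        problems.append("negative counts in events")
    if (pop_df["person_years"] < 0).any():
        problems.append("negative person-years in population")
    if problems:
        raise ValidationError(problems)

    years = tuple(sorted(pop_df["year"].unique()))
    strata = tuple(
        (b, s)
        for b, s in pop_df[["age_band", "sex"]].drop_duplicates().itertuples(
            index=False
        )
    )
    I, T, S = len(geo.area_ids), len(years), len(strata)
    apos = {a: i for i, a in enumerate(geo.area_ids)}
    ypos = {y: t for t, y in enumerate(years)}
    spos = {bs: s for s, bs in enumerate(strata)}

    py = np.zeros((I, T, S))
    for row in pop_df.itertuples(index=False):
        py[apos[row.area_id], ypos[row.year], spos[(row.age_band, row.sex)]] = (
            row.person_years
        )
    missing = int((py == 0).sum())
    pop = StratifiedPopulation(geo.area_ids, years, strata, py)

    stratified = {"age_band", "sex"} <= set(ev_df.columns)
    o_strat = None
    if stratified:
        o_strat = np.zeros((I, T, S), dtype=int)
        for row in ev_df.itertuples(index=False):
            key = (row.age_band, row.sex)
            if key not in spos:
                raise ValidationError(
                    [f"events stratum {key} absent from population table"]
                )
            if row.year not in ypos:
                raise ValidationError([f"events year {row.year} has no population"])
            o_strat[apos[row.area_id], ypos[row.year], spos[key]] += int(row.count)
        o = o_strat.sum(axis=2)
    else:
        o = np.zeros((I, T), dtype=int)
        for row in ev_df.itertuples(index=False):
            if row.year not in ypos:
                raise ValidationError([f"events year {row.year} has no population"])
            o[apos[row.area_id], ypos[row.year]] += int(row.count)

    exp_path = Path(events_path).parent / "expected.csv"
    if exp_path.exists():
        e = np.zeros((I, T))
        for row in read_csv(exp_path).itertuples(index=False):
            e[apos[row.area_id], ypos[row.year]] = row.expected
    elif o_strat is not None:
        e = expected_counts(o_strat, py)
    else:
        totals = py.sum(axis=2)
        pooled = o.sum() / totals.sum()
        e = pooled * totals

    panel = CountsPanel(
        area_ids=geo.area_ids,
        years=years,
        o=o,
        e=e,
        person_years=py.sum(axis=2),
        o_strat=o_strat,
        strata=strata if o_strat is not None else None,
    )
    _ = missing  # zero-filled strata are allowed; kept for future reporting
    return panel, pop, geo


# ----------------------------------------------------------------------
# map and trend exports

#: multiplicative cut points of the 7 risk categories, symmetric on the log
#: scale around RR = 1
RISK_BIN_RATIOS = (1.10, 1.25, 1.50)


def risk_bin(rr: float) -> int:
    """Categorical risk bin in 0..6; bin 3 straddles RR = 1 and
    ``bin(1/rr) == 6 - bin(rr)``."""
    r1, r2, r3 = RISK_BIN_RATIOS
    edges = [1 / r3, 1 / r2, 1 / r1, r1, r2, r3]
    return int(np.searchsorted(edges, rr, side="right"))


def export_risk_maps(
    summary: PosteriorSummary,
    geo: Geography | None = None,
    years: Sequence[int] | None = None,
) -> dict[int, dict]:
    """One GeoJSON FeatureCollection per year with per-area risk summaries.

    Falls back to table-like features with null geometry when polygons are
    unavailable.
    """
    geo = geo or summary.geo
    years = list(years) if years is not None else list(summary.years)
    ypos = {y: t for t, y in enumerate(summary.years)}
    out: dict[int, dict] = {}
    for y in years:
        t = ypos[y]
        features = []
        for i, a in enumerate(geo.area_ids):
            geom = (
                mapping(geo.geometry[a]) if geo.geometry is not None else None
            )
            rr = float(summary.rr_mean[i, t])
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "area_id": a,
                        "region_id": geo.parent[a],
                        "rr_mean": rr,
                        "rr_lo": float(summary.rr_lo[i, t]),
                        "rr_hi": float(summary.rr_hi[i, t]),
                        "risk_bin": risk_bin(rr),
                    },
                    "geometry": geom,
                }
            )
        out[y] = {"type": "FeatureCollection", "features": features}
    return out


def export_regional_trends(summary: PosteriorSummary) -> pd.DataFrame:
    """Long table of exp(v_j + gamma_t + delta_jt) per region and year.

    Columns: region_id, year, trend_mean, trend_lo, trend_hi (posterior mean
    and central 95% interval).
    """
    J = summary.geo.n_regions
    T = len(summary.years)
    D = summary.n_draws
    v = (summary.component_draws("v") if summary.v is not None
         else np.zeros((D, J)))
    g = (summary.component_draws("gamma") if summary.gamma is not None
         else np.zeros((D, T)))
    d = (summary.component_draws("delta") if summary.delta is not None
         else np.zeros((D, J, T)))
    curves = np.exp(v[:, :, None] + g[:, None, :] + d)  # (D, J, T)
    rows = []
    mean = curves.mean(axis=0)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    for j, r in enumerate(summary.geo.region_ids):
        for t, y in enumerate(summary.years):
            rows.append(
                {
                    "region_id": r,
                    "year": y,
                    "trend_mean": mean[j, t],
                    "trend_lo": lo[j, t],
                    "trend_hi": hi[j, t],
                }
            )
    return pd.DataFrame(rows)


def geometry_from_geojson(path: str | Path) -> dict[str, Polygon]:
    fc = json.loads(Path(path).read_text())
    return {
        f["properties"]["area_id"]: shape(f["geometry"])
        for f in fc["features"]
    }
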