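"""Nested two-level synthetic geographies.

The study system is a set of I health-care areas (HAs) nested in J regions
(autonomous communities, ACs).  Each area belongs to exactly one region.  A
synthetic planar geometry (Voronoi tessellation of random seed points on the
unit square) provides polygons for map exports and a shared-border adjacency
relation for the ICAR model variant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
from shapely.geometry import Polygon


class GeographyError(ValueError):
    """Raised when a geography violates the nesting/adjacency invariants."""


@dataclasses.dataclass(frozen=True)
class Geography:
    """Nested area/region structure with optional adjacency and polygons.

    Parameters
    ----------
    region_ids
        Ordered region identifiers (length J).
    area_ids
        Ordered area identifiers (length I).
    parent
        Map ``area_id -> region_id``; every area has exactly one parent.
    adjacency
        Optional set of unordered area-index pairs ``(a, b)`` with ``a < b``
        (positions in ``area_ids``), symmetric and irreflexive by
        construction.
    geometry
        Optional map ``area_id -> shapely.Polygon`` in abstract planar units.
    """

    region_ids: tuple[str, ...]
    area_ids: tuple[str, ...]
    parent: dict[str, str]
    adjacency: frozenset[tuple[int, int]] | None = None
    geometry: dict[str, Polygon] | None = None

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise GeographyError("duplicate region ids")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise GeographyError("duplicate area ids")
        regions = set(self.region_ids)
        for a in self.area_ids:
            if a not in self.parent:
                raise GeographyError(f"area {a!r} has no parent region")
            if self.parent[a] not in regions:
                raise GeographyError(
                    f"area {a!r} maps to unknown region {self.parent[a]!r}"
                )
        children = {r: 0 for r in self.region_ids}
        for a in self.area_ids:
            children[self.parent[a]] += 1
        empty = [r for r, k in children.items() if k == 0]
        if empty:
            raise GeographyError(f"regions without areas: {empty}")
        if self.adjacency is not None:
            for a, b in self.adjacency:
                if a == b:
                    raise GeographyError("self-adjacency is not allowed")
                if not (0 <= a < b < len(self.area_ids)):
                    raise GeographyError(f"adjacency pair out of range: {(a, b)}")

    # ------------------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def region_index(self) -> np.ndarray:
        """Position of each area's parent region in ``region_ids``."""
        pos = {r: j for j, r in enumerate(self.region_ids)}
        return np.array([pos[self.parent[a]] for a in self.area_ids], dtype=int)

    def areas_of(self, region_id: str) -> list[str]:
        return [a for a in self.area_ids if self.parent[a] == region_id]

    def adjacency_pairs(self) -> np.ndarray:
        """Adjacency as an ``(m, 2)`` integer array of area positions."""
        if self.adjacency is None:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.adjacency), dtype=int).reshape(-1, 2)

    def is_connected(self) -> bool:
        """Whether the area adjacency graph has a single component."""
        if self.adjacency is None:
            return self.n_areas == 1
        pairs = self.adjacency_pairs()
        n = self.n_areas
        if n == 1:
            return True
        if pairs.size == 0:
            return False
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, _ = connected_components(g, directed=False)
        return ncomp == 1

    def subset(self, keep_regions: Sequence[str]) -> "Geography":
        """Geography restricted to ``keep_regions`` (order preserved).

        Adjacency is re-indexed to the surviving areas; pairs crossing the cut
        are dropped.  Used by the exclude-and-refit sensitivity analysis.
        """
        keep = [r for r in self.region_ids if r in set(keep_regions)]
        if not keep:
            raise GeographyError("subset would keep no regions")
        areas = [a for a in self.area_ids if self.parent[a] in set(keep)]
        old_pos = {a: i for i, a in enumerate(self.area_ids)}
        new_pos = {old_pos[a]: i for i, a in enumerate(areas)}
        adjacency = None
        if self.adjacency is not None:
            adjacency = frozenset(
                (new_pos[a], new_pos[b])
                for a, b in self.adjacency
                if a in new_pos and b in new_pos
            )
        geometry = None
        if self.geometry is not None:
            geometry = {a: self.geometry[a] for a in areas}
        return Geography(
            region_ids=tuple(keep),
            area_ids=tuple(areas),
            parent={a: self.parent[a] for a in areas},
            adjacency=adjacency,
            geometry=geometry,
        )


def _resolve_sizes(J: int, areas_per_region: int | Sequence[int]) -> list[int]:
    if isinstance(areas_per_region, (int, np.integer)):
        sizes = [int(areas_per_region)] * J
    else:
        sizes = [int(k) for k in areas_per_region]
        if len(sizes) != J:
            raise GeographyError(
                f"areas_per_region has length {len(sizes)}, expected J={J}"
            )
    if any(k < 1 for k in sizes):
        raise GeographyError("every region must contain at least one area")
    return sizes


def _bounded_voronoi_polygons(points: np.ndarray) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the unit square.

    Cells are bounded by mirroring the point set across the four sides before
    tessellating, so every original point gets a finite convex cell.
    """
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, 1.0), (1, 0.0), (1, 1.0)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # cells are convex; sort vertices by angle around the centroid
        c = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
        polys.append(Polygon(verts[order]))
    return polys


def make_nested_geography(
    J: int,
    areas_per_region: int | Sequence[int],
    seed: int,
    *,
    with_geometry: bool = True,
) -> Geography:
    """Draw a random nested geography with ``J`` regions.

    Areas are Voronoi cells of uniform seed points on the unit square;
    adjacency is the Delaunay dual (cells sharing a border).  Regions are
    contiguous strips of areas sorted by their first coordinate, which honours
    an exact per-region size specification.  Deterministic given ``seed``.
    """
    if J < 1:
        raise GeographyError("J must be >= 1")
    sizes = _resolve_sizes(J, areas_per_region)
    I = sum(sizes)
    rng = np.random.default_rng(seed)
    points = rng.uniform(size=(I, 2))
    order = np.argsort(points[:, 0], kind="stable")
    points = points[order]

    region_ids = tuple(f"AC{j + 1:02d}" for j in range(J))
    area_ids = tuple(f"HA{i + 1:03d}" for i in range(I))
    parent: dict[str, str] = {}
    i = 0
    for j, k in enumerate(sizes):
        for _ in range(k):
            parent[area_ids[i]] = region_ids[j]
            i += 1

    if I == 1:
        geometry = {area_ids[0]: Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])}
        return Geography(
            region_ids,
            area_ids,
            parent,
            adjacency=frozenset(),
            geometry=geometry if with_geometry else None,
        )

    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, 1.0), (1, 0.0), (1, 1.0)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    pairs = set()
    for a, b in vor.ridge_points:
        if a < I and b < I and a != b:
            pairs.add((min(int(a), int(b)), max(int(a), int(b))))

    geometry = None
    if with_geometry:
        polys = _bounded_voronoi_polygons(points)
        geometry = dict(zip(area_ids, polys))

    return Geography(
        region_ids, area_ids, parent, adjacency=frozenset(pairs), geometry=geometry
    )
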