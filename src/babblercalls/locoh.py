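"""Adaptive local convex hull (a-LoCoH) territory estimation.

The utilisation distribution of a group is estimated from its GPS fixes with
the adaptive "sphere-of-influence" local convex hull method: around every fix
(the *root*) a local convex hull is built from the nearest neighbours whose
cumulative distance to the root fits within a budget ``a`` (metres).  Hulls
are then sorted densest-first (ascending area) and unioned until the union
covers the required fraction of fixes, producing density isopleths — the
smallest-area polygons encompassing 50%, 75% and 95% of the fixes by
default.  The 95% isopleth is taken as the territory.

Degenerate inputs (collinear or duplicated fixes) yield zero-area hulls,
which sort first and contribute their covered points without area; a fully
degenerate input (all fixes identical) is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .core_io import Fix, ValidationError

DEFAULT_LEVELS: tuple[float, ...] = (0.50, 0.75, 0.95)


class DegenerateTerritoryError(ValueError):
    """All fixes coincide (or are otherwise too degenerate to yield an area)."""


@dataclass(frozen=True)
class LocalHull:
    """Convex hull of one root fix and its adaptive neighbour set."""

    root_index: int
    member_indices: frozenset[int]
    polygon: BaseGeometry
    area_m2: float


@dataclass
class Territory:
    """Nested density isopleths of one group-season.

    ``isopleths`` maps level (fraction of fixes covered) to a (multi)polygon;
    levels p < q satisfy isopleth(p) within isopleth(q).  ``a_value`` records
    the neighbour-budget used, for provenance.
    """

    group_id: str
    season: str
    isopleths: dict[float, BaseGeometry]
    areas_ha: dict[float, float]
    a_value: float
    n_fixes: int

    def isopleth(self, level: float) -> BaseGeometry:
        return self.isopleths[level]

    @property
    def levels(self) -> list[float]:
        return sorted(self.isopleths)


def _as_points(points: Sequence | np.ndarray) -> np.ndarray:
    arr = np.asarray(
        [(p.x, p.y) if isinstance(p, Fix) else (p[0], p[1]) for p in points]
        if not (isinstance(points, np.ndarray) and points.ndim == 2)
        else points,
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite coordinates in fix set")
    return arr


def select_neighbours_adaptive(
    points: Sequence | np.ndarray, root: int, a: float
) -> frozenset[int]:
    """Adaptive neighbour set of ``root``: nearest points whose cumulative
    distance to the root stays within ``a`` metres.

    Points are sorted by ascending distance to the root (ties broken by
    ascending index, so the result is deterministic); the maximal prefix with
    running distance sum <= a is kept, plus the root itself.
    """
    pts = _as_points(points)
    n = len(pts)
    if not 0 <= root < n:
        raise IndexError(f"root index {root} out of range for {n} points")
    if a < 0:
        raise ValueError("a must be non-negative")
    d = np.hypot(pts[:, 0] - pts[root, 0], pts[:, 1] - pts[root, 1])
    order = np.argsort(d, kind="stable")
    order = order[order != root]
    running = np.cumsum(d[order])
    keep = order[running <= a]
    return frozenset([root, *keep.tolist()])


def build_local_hulls(points: Sequence | np.ndarray, a: float) -> list[LocalHull]:
    """One local convex hull rooted at every fix.

    Hulls with fewer than three distinct member points are degenerate
    (a point or segment) and get area 0.
    """
    pts = _as_points(points)
    hulls: list[LocalHull] = []
    for root in range(len(pts)):
        members = select_neighbours_adaptive(pts, root, a)
        geom = MultiPoint(pts[sorted(members)]).convex_hull
        hulls.append(LocalHull(root, members, geom, float(geom.area)))
    return hulls


def _sorted_hulls(hulls: Sequence[LocalHull]) -> list[LocalHull]:
    # densest-first union: ascending area, then larger member sets first,
    # then root index — fully deterministic
    return sorted(
        hulls, key=lambda h: (h.area_m2, -len(h.member_indices), h.root_index)
    )


def compute_isopleths(
    hulls: Sequence[LocalHull],
    levels: Iterable[float],
    points: Sequence | np.ndarray,
) -> tuple[dict[float, BaseGeometry], dict[float, float]]:
    """Union hulls densest-first into the smallest-area isopleths.

    The isopleth at level ``q`` is the union of the minimal prefix of
    area-sorted hulls whose union covers at least ceil(q * n) of the n fixes
    (boundary-inclusive point-in-polygon counting; duplicate fixes each
    count).  Because prefixes nest, isopleths nest by construction.
    """
    pts = _as_points(points)
    n = len(pts)
    levels = sorted(set(float(q) for q in levels))
    if not levels or levels[0] <= 0 or levels[-1] > 1:
        raise ValueError("levels must lie in (0, 1]")
    ordered = _sorted_hulls(hulls)
    pt_geoms = shapely.points(pts)
    covered = np.zeros(n, dtype=bool)
    counts = np.empty(len(ordered), dtype=int)
    for k, hull in enumerate(ordered):
        covered |= shapely.covers(hull.polygon, pt_geoms)
        counts[k] = int(covered.sum())
    isopleths: dict[float, BaseGeometry] = {}
    areas: dict[float, float] = {}
    for q in levels:
        need = int(np.ceil(q * n))
        idx = int(np.searchsorted(counts, need, side="left"))
        if idx >= len(ordered):  # cannot happen: the full union covers all points
            idx = len(ordered) - 1
        geom = unary_union([h.polygon for h in ordered[: idx + 1]])
        isopleths[q] = geom
        areas[q] = area_hectares(geom)
    if all(a == 0.0 for a in areas.values()):
        raise DegenerateTerritoryError(
            "all isopleths have zero area (degenerate fix set)"
        )
    return isopleths, areas


def choose_a(points: Sequence | np.ndarray) -> float:
    """Default neighbour budget: the maximum pairwise distance among fixes.

    This is the standard starting heuristic for the adaptive method; it is
    user-overridable in config and recorded in the Territory for provenance.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("need at least two points to choose a")
    from scipy.spatial.distance import pdist

    dmax = float(pdist(pts).max())
    if dmax == 0.0:
        raise DegenerateTerritoryError("all points identical; cannot choose a")
    return dmax


def area_hectares(geom: BaseGeometry) -> float:
    """Planar polygon area in hectares (multi-part summed, holes subtracted)."""
    if not geom.is_valid:
        raise ValidationError("invalid geometry passed to area_hectares")
    return float(geom.area) / 10_000.0


def estimate_territory(
    fixes: Sequence[Fix] | np.ndarray,
    group_id: str,
    season: str = "",
    a: float | None = None,
    levels: Iterable[float] = DEFAULT_LEVELS,
) -> Territory:
    """End-to-end a-LoCoH: choose ``a`` (if not given), build local hulls,
    and union them into the requested density isopleths."""
    pts = _as_points(fixes)
    a_value = choose_a(pts) if a is None else float(a)
    hulls = build_local_hulls(pts, a_value)
    isopleths, areas = compute_isopleths(hulls, levels, pts)
    return Territory(
        group_id=group_id,
        season=season,
        isopleths=isopleths,
        areas_ha=areas,
        a_value=a_value,
        n_fixes=len(pts),
    )
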